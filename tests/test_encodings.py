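"""Encoder correctness against brute-force oracles, family identities and
the shared encoder contract (ordering, dropping, normalisation)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import make_dataset
from pepbench.datasets import AMINO_ACIDS
from pepbench.encode import EncodingSpec, IndexTable, encode, registry
from pepbench.encode import tables
from pepbench.errors import (
    AlignmentRequiredError,
    EmptyEncodingError,
    InvalidIndexError,
    RegistryError,
)

KD = tables.AAINDEX_SUBSET["KYTJ820101"]


def single(seq: str, group: str, params=None):
    """Encode one sequence; return its feature row or None if dropped."""
    ds = make_dataset(seq, "ACDEFGHIKLMNPQRSTVWY" * 2, labels=[1, 0])
    enc = encode(ds, EncodingSpec(group, params or {}))
    if "s0" not in enc.row_ids:
        return None
    return enc.matrix[enc.row_ids.index("s0")]


class TestCompositionFamily:
    def test_aac_counts(self):
        row = single("AAC", "aac")
        expect = {a: 0.0 for a in AMINO_ACIDS} | {"A": 2 / 3, "C": 1 / 3}
        np.testing.assert_allclose(row, [expect[a] for a in AMINO_ACIDS])

    def test_aac_uniform_on_full_alphabet(self):
        np.testing.assert_allclose(single(AMINO_ACIDS, "aac"), np.full(20, 0.05))

    def test_dpc_overlapping(self):
        row = single("AAA", "dpc")
        assert row[0] == 1.0 and row.sum() == 1.0  # feature AA carries all mass

    @pytest.mark.parametrize("seq", ["ACDC", "AAAA", "KRKRH", "ACDEFG"])
    @pytest.mark.parametrize(
        "group,k,classes",
        [("aac", 1, None), ("dpc", 2, None), ("tpc", 3, None),
         ("gaac", 1, oracles.FIVE), ("gdpc", 2, oracles.FIVE), ("gtpc", 3, oracles.FIVE)],
    )
    def test_kmer_oracle(self, seq, group, k, classes):
        expected = oracles.kmer_freqs(seq, k, classes=classes)
        row = single(seq, group)
        if expected is None:
            assert row is None
        else:
            np.testing.assert_allclose(row, expected, atol=1e-12)


class TestGappedPairs:
    def test_gap0_enumeration(self):
        row = single("AACA", "cksaap", {"gmax": 0})
        np.testing.assert_allclose(row, oracles.cksaap("AACA", 0))
        # pairs AA, AC, CA each once out of three
        assert sorted(row[row > 0]) == pytest.approx([1 / 3] * 3)

    def test_gap1_block(self):
        row = single("AACA", "cksaap", {"gmax": 1})
        block = row[400:]
        # gap-1 pairs: (A,C) and (A,A)
        nz = {i for i, v in enumerate(block) if v > 0}
        a, c = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("C")
        assert nz == {a * 20 + c, a * 20 + a}
        assert block.sum() == pytest.approx(1.0)

    def test_dimension(self):
        assert single("ACDEFACDEF", "cksaap", {"gmax": 3}).size == 1600

    @pytest.mark.parametrize("seq", ["ACDCA", "AAAAAA", "KRHDE"])
    @pytest.mark.parametrize("group,classes", [("cksaap", None), ("cksaagp", oracles.FIVE)])
    def test_oracle(self, seq, group, classes):
        np.testing.assert_allclose(
            single(seq, group, {"gmax": 2}),
            oracles.cksaap(seq, 2, classes=classes),
            atol=1e-12,
        )


class TestSlidingWindow:
    def test_single_window_is_composition(self):
        ds = make_dataset("AAAA", "ACAC", labels=[1, 0])
        enc = encode(ds, EncodingSpec("eaac", {"window": 4}))
        assert enc.matrix.shape == (2, 20)
        assert enc.matrix[0][AMINO_ACIDS.index("A")] == 1.0

    def test_too_short_dropped_and_logged(self):
        ds = make_dataset("ACD", "AC", labels=[1, 0])
        enc = encode(ds, EncodingSpec("eaac", {"window": 3}))
        assert enc.row_ids == ["s0"] and "s1" in enc.dropped

    def test_oracle(self):
        ds = make_dataset("ACDEFG", "AAAAAA", labels=[1, 0])
        enc = encode(ds, EncodingSpec("egaac", {"window": 3}))
        np.testing.assert_allclose(
            enc.matrix[0], oracles.sliding_composition("ACDEFG", 3, classes=oracles.FIVE)
        )


class TestAutocorrelation:
    def test_constant_index_rejected(self):
        from pepbench.encode import autocorr

        flat = IndexTable("flat", tuple([1.0] * 20))
        ds = make_dataset("ACDEF", "FEDCA", labels=[1, 0])
        with pytest.raises(InvalidIndexError):
            autocorr.moran(ds, lag=1, indices=[flat])

    @pytest.mark.parametrize("variant", ["moran", "geary", "nmbroto"])
    @pytest.mark.parametrize("seq", ["ACDC", "KRKRKR", "ACDEFGHIKL"])
    def test_direct_formula_oracle(self, variant, seq):
        from pepbench.encode import autocorr

        ds = make_dataset(seq, "ACDEFGHIKL", labels=[1, 0])
        table = IndexTable.from_mapping("KYTJ820101", KD)
        enc = getattr(autocorr, variant)(ds, lag=2, indices=[table])
        np.testing.assert_allclose(
            enc.matrix[0], oracles.autocorrelation(seq, KD, 2, variant), atol=1e-12
        )

    def test_nmbroto_constant_sequence_closed_form(self):
        from pepbench.encode import autocorr

        table = IndexTable.from_mapping("KYTJ820101", KD)
        v = table.standardized()[AMINO_ACIDS.index("W")]
        ds = make_dataset("WWWWWW", "ACDEFG", labels=[1, 0])
        enc = autocorr.nmbroto(ds, lag=3, indices=[table])
        np.testing.assert_allclose(enc.matrix[0], [v**2] * 3, atol=1e-12)


class TestCTD:
    def test_composition_single_class(self):
        # sequence entirely hydrophobic-class for the hydrophobicity property
        row = single("CLVW", "ctdc")
        np.testing.assert_allclose(row[:3], [0, 0, 1])

    def test_transition_count(self):
        # classes "aabb" -> one 1<->2 transition out of 3 adjacent pairs
        hydro = tables.CTD_PROPERTIES["hydrophobicity"]
        np.testing.assert_allclose(oracles.ctd_transition("RRGG", hydro), [1 / 3, 0, 0])
        row = single("RRGG", "ctdt")
        np.testing.assert_allclose(row[:3], [1 / 3, 0, 0])

    def test_distribution_last_residue_landmarks(self):
        # polar class 1 (hydrophobicity property) appears only at final position
        seq = "G" * 9 + "R"
        row = single(seq, "ctdd")
        np.testing.assert_allclose(row[:5], [100.0] * 5)

    @pytest.mark.parametrize("seq", ["ACDEFGHIKL", "RKEDQN", "GGGG"])
    def test_all_parts_oracle(self, seq):
        for group, fn in [
            ("ctdc", oracles.ctd_composition),
            ("ctdt", oracles.ctd_transition),
            ("ctdd", oracles.ctd_distribution),
        ]:
            expected = []
            for prop in tables.CTD_PROPERTIES.values():
                expected.extend(fn(seq, prop))
            np.testing.assert_allclose(single(seq, group), expected, atol=1e-12)


class TestTriads:
    def test_single_class_sequence(self):
        row = single("AAAA", "ctriad")
        assert row.sum() == 1.0 and row[0] == 1.0  # class-0 triad only

    def test_length_rule_2k_plus_3(self):
        ds = make_dataset("ACDE", "ACDEFGHIK", labels=[1, 0])
        enc = encode(ds, EncodingSpec("ksctriad", {"kmax": 1}))
        assert "s0" in enc.dropped and enc.row_ids == ["s1"]

    def test_dimension(self):
        assert single("ACDEFGHIKLMNP", "ksctriad", {"kmax": 2}).size == 1029

    @pytest.mark.parametrize("seq", ["ACDEFGHIK", "AAAACCCCD"])
    def test_oracle(self, seq):
        row = single(seq, "ksctriad", {"kmax": 1})
        expected = oracles.triad_block(seq, 0) + oracles.triad_block(seq, 1)
        np.testing.assert_allclose(row, expected, atol=1e-12)


class TestSequenceOrder:
    def test_identical_residues_zero_coupling(self):
        row = single("AAAAA", "socnumber", {"nlag": 2})
        np.testing.assert_allclose(row, 0.0)

    def test_qsorder_all_A_first_block(self):
        row = single("AAAAA", "qsorder", {"nlag": 2, "weight": 0.1})
        # zero couplings -> composition block: A feature 1, others 0
        np.testing.assert_allclose(row[:20], np.eye(20)[AMINO_ACIDS.index("A")])

    def test_nlag_too_long_drops(self):
        ds = make_dataset("ACD", "ACDEFGHIKL", labels=[1, 0])
        enc = encode(ds, EncodingSpec("socnumber", {"nlag": 4}))
        assert "s0" in enc.dropped

    @pytest.mark.parametrize("seq", ["ACDEF", "KRHWY"])
    def test_oracles(self, seq):
        soc_expected = []
        for dist in tables.ORDER_DISTANCE_MATRICES.values():
            soc_expected.extend(oracles.coupling(seq, dist, 2))
        np.testing.assert_allclose(single(seq, "socnumber", {"nlag": 2}), soc_expected)
        np.testing.assert_allclose(
            single(seq, "qsorder", {"nlag": 2, "weight": 0.1}),
            oracles.qsorder(seq, 2, 0.1),
            atol=1e-12,
        )


class TestPseudoComposition:
    @pytest.mark.parametrize("group", ["paac", "apaac"])
    def test_row_sums_to_one(self, group):
        row = single("ACDEFGHIKL", group, {"lam": 3, "weight": 0.05})
        assert row.sum() == pytest.approx(1.0)

    def test_weight_zero_reduces_to_aac(self):
        seq = "ACDEFGHIKL"
        for group in ("paac", "apaac"):
            row = single(seq, group, {"lam": 2, "weight": 0.0})
            np.testing.assert_allclose(row[:20], single(seq, "aac"), atol=1e-12)

    def test_lambda_too_long_drops(self):
        ds = make_dataset("ACD", "ACDEFGHIKL", labels=[1, 0])
        enc = encode(ds, EncodingSpec("paac", {"lam": 5}))
        assert "s0" in enc.dropped

    @pytest.mark.parametrize("seq", ["ACDEFG", "KKRRHH"])
    def test_oracles(self, seq):
        np.testing.assert_allclose(
            single(seq, "paac", {"lam": 2, "weight": 0.05}),
            oracles.paac(seq, 2, 0.05),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            single(seq, "apaac", {"lam": 2, "weight": 0.05}),
            oracles.apaac(seq, 2, 0.05),
            atol=1e-12,
        )


class TestPsekraac:
    def test_identity_reduction_is_aac(self):
        seq = "ACDEFGHIKLKK"
        row = single(seq, "psekraac", {"clusters": 20, "ktuple": 1, "gap": 0})
        np.testing.assert_allclose(row, single(seq, "aac"))

    def test_feature_count(self):
        assert single("ACDEF", "psekraac", {"clusters": 5, "ktuple": 2}).size == 25

    def test_two_cluster_tuples_oracle(self):
        classes = tables.PSEKRAAC_FAMILIES["type1"][2]
        seq = "CACA"  # alternating class pattern
        row = single(seq, "psekraac", {"clusters": 2, "ktuple": 2, "gap": 0})
        np.testing.assert_allclose(row, oracles.psekraac(seq, classes, 2, 0))

    def test_gapped_tuples_oracle(self):
        classes = tables.PSEKRAAC_FAMILIES["type1"][5]
        seq = "ACDEFGHIK"
        row = single(seq, "psekraac", {"clusters": 5, "ktuple": 2, "gap": 1})
        np.testing.assert_allclose(row, oracles.psekraac(seq, classes, 2, 1))


class TestPerResidue:
    def test_binary_two_ones(self):
        ds = make_dataset("AC", "CA", labels=[1, 0])
        enc = encode(ds, EncodingSpec("binary"))
        row = enc.matrix[0]
        assert row.size == 40 and row.sum() == 2
        assert row[AMINO_ACIDS.index("A")] == 1
        assert row[20 + AMINO_ACIDS.index("C")] == 1

    def test_ragged_without_aligner_errors(self):
        ds = make_dataset("ACD", "ACDE", labels=[1, 0])
        with pytest.raises(AlignmentRequiredError):
            encode(ds, EncodingSpec("binary"))

    def test_aligner_hook_and_gap_zeros(self):
        from pepbench.encode import residue

        ds = make_dataset("ACD", "ACDE", labels=[1, 0])
        aligner = lambda seqs: ["ACD-", "ACDE"]  # noqa: E731
        enc = residue.binary(ds, aligner=aligner)
        assert enc.matrix.shape == (2, 80)
        np.testing.assert_allclose(enc.matrix[0][60:], 0.0)  # gap column all-zero

    @pytest.mark.parametrize(
        "group,oracle",
        [("binary", oracles.one_hot), ("zscale", oracles.zscale),
         ("aaindex", lambda s: oracles.aaindex_profile(s, "KYTJ820101"))],
    )
    def test_profiles_match_oracle(self, group, oracle):
        ds = make_dataset("ACDEF", "KLMNP", labels=[1, 0])
        enc = encode(ds, EncodingSpec(group))
        np.testing.assert_allclose(enc.matrix[0], oracle("ACDEF"))

    def test_blosum62_rows_from_library_matrix(self):
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        ds = make_dataset("AW", "WA", labels=[1, 0])
        enc = encode(ds, EncodingSpec("blosum62"))
        np.testing.assert_allclose(
            enc.matrix[0][:20], [float(mat["A", b]) for b in AMINO_ACIDS]
        )


class TestDistanceFrequency:
    def test_four_As_two_bins(self):
        row = single("AAAA", "distance_frequency", {"bins": 2})
        a = AMINO_ACIDS.index("A")
        np.testing.assert_allclose(row[2 * a : 2 * a + 2], [0.5, 0.5])

    def test_absent_residue_all_zero(self):
        row = single("AAAA", "distance_frequency", {"bins": 3})
        w = AMINO_ACIDS.index("W")
        np.testing.assert_allclose(row[3 * w : 3 * w + 3], 0.0)

    def test_bins_sum_to_aac(self):
        seq = "ACDACDKKR"
        row = single(seq, "distance_frequency", {"bins": 4}).reshape(20, 4)
        np.testing.assert_allclose(row.sum(axis=1), single(seq, "aac"), atol=1e-12)


class TestFCGR:
    def test_mass_conserved(self):
        seq = "ACDEFGHIKL"
        row = single(seq, "fcgr", {"resolution": 4})
        assert row.sum() == pytest.approx(1.0)

    def test_single_symbol_converges_to_corner(self):
        # all-K sequence: positive class (index 2), corner (0, 1) -> cell [3, 0]
        row = single("K" * 30, "fcgr", {"resolution": 4}).reshape(4, 4)
        assert row[3, 0] > 0.9

    @pytest.mark.parametrize("seq", ["ACAC", "ACDEFGHIKL"])
    def test_step_by_step_oracle(self, seq):
        np.testing.assert_allclose(
            single(seq, "fcgr", {"resolution": 2}), oracles.fcgr(seq, 2)
        )


class TestNgram:
    def test_reduced_trigram_oracle(self):
        seq = "CACACAC"  # alternates between the two type1 2-cluster classes
        row = single(seq, "ngram", {"n": 3, "reduction": "conjoint"})
        np.testing.assert_allclose(
            row, oracles.kmer_freqs(seq, 3, classes=oracles.TRIAD7)
        )


class TestEncoderContract:
    """Shared invariants: determinism, ordering, drop bookkeeping."""

    SPECS = [
        EncodingSpec("aac"), EncodingSpec("cksaap", {"gmax": 1}),
        EncodingSpec("ctdd"), EncodingSpec("moran", {"lag": 2}),
        EncodingSpec("paac", {"lam": 2}), EncodingSpec("fcgr", {"resolution": 4}),
        EncodingSpec("psekraac", {"clusters": 5, "ktuple": 2, "gap": 0}),
        EncodingSpec("ksctriad", {"kmax": 1}), EncodingSpec("socnumber", {"nlag": 2}),
        EncodingSpec("distance_frequency", {"bins": 3}),
    ]

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.id)
    def test_rows_plus_dropped_partition_input(self, spec, biased_dataset):
        enc = encode(biased_dataset, spec)
        assert len(enc.row_ids) + len(enc.dropped) == len(biased_dataset)
        assert [i for i in biased_dataset.ids if i not in enc.dropped] == enc.row_ids

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.id)
    def test_deterministic(self, spec, toy_dataset):
        a = encode(toy_dataset, spec)
        b = encode(toy_dataset, spec)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_all_dropped_raises(self):
        ds = make_dataset("ACD", "EFG", labels=[1, 0])
        with pytest.raises(EmptyEncodingError):
            encode(ds, EncodingSpec("socnumber", {"nlag": 10}))

    def test_unknown_group_rejected(self, toy_dataset):
        with pytest.raises(RegistryError):
            encode(toy_dataset, EncodingSpec("nope"))

    @given(st.text(alphabet="ACDE", min_size=4, max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_composition_encoders_normalised(self, seq):
        for group in ("aac", "dpc", "gaac", "ngram"):
            row = single(seq, group)
            assert np.all(row >= 0)
            assert row.sum() == pytest.approx(1.0)
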