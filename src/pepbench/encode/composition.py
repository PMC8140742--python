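"""Compositional encoders: k-mer, grouped, gapped-pair, sliding-window,
n-gram and positional distance-frequency descriptors.

All of these are counting encoders: non-negative feature vectors with an
exact normalisation (sum-to-1 per row or per gap/window block).
"""

from __future__ import annotations

from itertools import product

import numpy as np

from pepbench.datasets import AMINO_ACIDS, PeptideDataset
from pepbench.encode import tables
from pepbench.encode.base import EncodedDataset, EncodingSpec, TooShort, encode_rows, register
from pepbench.errors import AlignmentRequiredError

GROUP_NAMES = tuple(tables.FIVE_GROUPS)
_GROUP_OF = tables.group_index(tables.FIVE_GROUPS)


def _kmer_names(alphabet: tuple[str, ...] | str, k: int) -> list[str]:
    return ["".join(t) for t in product(list(alphabet), repeat=k)]


def _kmer_freqs(symbols: list[int], n_sym: int, k: int) -> np.ndarray:
    """Overlapping k-mer relative frequencies of an integer-coded sequence."""
    n = len(symbols) - k + 1
    if n < 1:
        raise TooShort(f"length {len(symbols)} < k={k}")
    counts = np.zeros(n_sym**k)
    for i in range(n):
        code = 0
        for j in range(k):
            code = code * n_sym + symbols[i + j]
        counts[code] += 1
    return counts / n


def _codes(seq: str) -> list[int]:
    return [AMINO_ACIDS.index(a) for a in seq]


def _gcodes(seq: str) -> list[int]:
    return [_GROUP_OF[a] for a in seq]


def _make_kmer_encoder(name: str, k: int, grouped: bool):
    alphabet = GROUP_NAMES if grouped else AMINO_ACIDS
    names = [f"{name}.{m}" for m in _kmer_names(alphabet, k)]
    coder = _gcodes if grouped else _codes
    n_sym = len(alphabet)

    def enc(dataset: PeptideDataset, spec: EncodingSpec | None = None) -> EncodedDataset:
        spec = spec or EncodingSpec(name)
        return encode_rows(dataset, spec, names, lambda s: _kmer_freqs(coder(s), n_sym, k))

    enc.__doc__ = f"{'Grouped ' if grouped else ''}{k}-mer relative frequencies ({name})."
    enc.__name__ = name
    return register(name)(enc)


aac = _make_kmer_encoder("aac", 1, grouped=False)
dpc = _make_kmer_encoder("dpc", 2, grouped=False)
tpc = _make_kmer_encoder("tpc", 3, grouped=False)
gaac = _make_kmer_encoder("gaac", 1, grouped=True)
gdpc = _make_kmer_encoder("gdpc", 2, grouped=True)
gtpc = _make_kmer_encoder("gtpc", 3, grouped=True)


def _pair_block(symbols: list[int], n_sym: int, gap: int) -> np.ndarray:
    """Relative frequencies of symbol pairs (i, i+gap+1); block sums to 1."""
    n = len(symbols) - gap - 1
    if n < 1:
        raise TooShort(f"length {len(symbols)} too short for gap {gap}")
    counts = np.zeros(n_sym * n_sym)
    for i in range(n):
        counts[symbols[i] * n_sym + symbols[i + gap + 1]] += 1
    return counts / n


def _make_gapped_pair_encoder(name: str, grouped: bool):
    alphabet = GROUP_NAMES if grouped else AMINO_ACIDS
    pair_names = _kmer_names(alphabet, 2)
    coder = _gcodes if grouped else _codes
    n_sym = len(alphabet)

    def enc(
        dataset: PeptideDataset, gmax: int = 2, spec: EncodingSpec | None = None
    ) -> EncodedDataset:
        spec = spec or EncodingSpec(name, {"gmax": gmax})
        names = [f"{name}.g{g}.{p}" for g in range(gmax + 1) for p in pair_names]

        def row(s: str) -> np.ndarray:
            sym = coder(s)
            return np.concatenate([_pair_block(sym, n_sym, g) for g in range(gmax + 1)])

        return encode_rows(dataset, spec, names, row)

    enc.__doc__ = (
        f"Composition of k-spaced {'group' if grouped else 'amino-acid'} pairs "
        f"for every gap 0..gmax ({name})."
    )
    enc.__name__ = name
    return register(name, {"gmax": lambda v: isinstance(v, int) and 0 <= v <= 9}, {"gmax": 2})(enc)


cksaap = _make_gapped_pair_encoder("cksaap", grouped=False)
cksaagp = _make_gapped_pair_encoder("cksaagp", grouped=True)


def _make_sliding_encoder(name: str, grouped: bool):
    alphabet = GROUP_NAMES if grouped else AMINO_ACIDS
    coder = _gcodes if grouped else _codes
    n_sym = len(alphabet)

    def enc(
        dataset: PeptideDataset, window: int = 5, spec: EncodingSpec | None = None
    ) -> EncodedDataset:
        spec = spec or EncodingSpec(name, {"window": window})

        def row(s: str) -> np.ndarray:
            if len(s) < window:
                raise TooShort(f"length {len(s)} < window {window}")
            sym = coder(s)
            blocks = []
            for start in range(len(s) - window + 1):
                counts = np.zeros(n_sym)
                for j in range(start, start + window):
                    counts[sym[j]] += 1
                blocks.append(counts / window)
            return np.concatenate(blocks)

        # the feature count depends on sequence length, so equal lengths are
        # required once too-short records are dropped
        lengths = {len(r.sequence) for r in dataset.records if len(r.sequence) >= window}
        if len(lengths) > 1:
            raise AlignmentRequiredError(
                f"{name}: sliding-window composition needs equal-length (aligned) "
                f"sequences, got lengths {sorted(lengths)}"
            )
        length = next(iter(lengths)) if lengths else window
        names = [
            f"{name}.w{start + 1}.{m}"
            for start in range(length - window + 1)
            for m in (list(alphabet))
        ]
        return encode_rows(dataset, spec, names, row)

    enc.__doc__ = (
        f"Sliding-window {'group' if grouped else 'amino-acid'} composition ({name}): "
        "per-window composition concatenated over all windows."
    )
    enc.__name__ = name
    return register(
        name, {"window": lambda v: isinstance(v, int) and v >= 1}, {"window": 5}
    )(enc)


eaac = _make_sliding_encoder("eaac", grouped=False)
egaac = _make_sliding_encoder("egaac", grouped=True)


@register(
    "ngram",
    {
        "n": lambda v: isinstance(v, int) and 1 <= v <= 4,
        "reduction": lambda v: v is None or v in ("conjoint", "fcgr", "five"),
    },
    {"n": 2, "reduction": None},
)
def ngram(
    dataset: PeptideDataset,
    n: int = 2,
    reduction: str | None = None,
    spec: EncodingSpec | None = None,
) -> EncodedDataset:
    """n-gram relative frequencies over the full or a reduced alphabet.

    With no reduction, ``n=1`` coincides with aac and ``n=2`` with dpc.
    """
    spec = spec or EncodingSpec("ngram", {"n": n, "reduction": reduction})
    if reduction is None:
        coder, n_sym, symbols = _codes, 20, list(AMINO_ACIDS)
    else:
        classes = {
            "conjoint": tables.CONJOINT_TRIAD_CLASSES,
            "fcgr": tables.FCGR_CLASSES,
            "five": tuple(tables.FIVE_GROUPS.values()),
        }[reduction]
        gmap = tables.group_index(classes)
        coder = lambda s: [gmap[a] for a in s]  # noqa: E731
        n_sym, symbols = len(classes), [f"c{i}" for i in range(len(classes))]
    names = [f"ngram.{'.'.join(t)}" for t in product(symbols, repeat=n)]
    return encode_rows(dataset, spec, names, lambda s: _kmer_freqs(coder(s), n_sym, n))


@register(
    "distance_frequency",
    {"bins": lambda v: isinstance(v, int) and v >= 1},
    {"bins": 4},
)
def distance_frequency(
    dataset: PeptideDataset, bins: int = 4, spec: EncodingSpec | None = None
) -> EncodedDataset:
    """Positional residue-frequency histogram.

    Each residue position i (1-based) is normalised to (i-1)/(L-1) in
    [0, 1] (0 for a length-1 sequence) and binned into ``bins`` equal-width
    bins; the feature for (amino acid a, bin b) is the count of a in bin b
    divided by L.  Summing a residue's bins recovers its aac value, and
    ``bins=1`` reduces exactly to aac.

    This positional histogram is a documented package default for the
    distance-frequency descriptor family; see the methods note.
    """
    spec = spec or EncodingSpec("distance_frequency", {"bins": bins})
    names = [f"dfreq.{a}.b{b}" for a in AMINO_ACIDS for b in range(bins)]

    def row(s: str) -> np.ndarray:
        length = len(s)
        out = np.zeros(20 * bins)
        for i, a in enumerate(s):
            pos = 0.0 if length == 1 else i / (length - 1)
            b = min(int(pos * bins), bins - 1)
            out[AMINO_ACIDS.index(a) * bins + b] += 1
        return out / length

    return encode_rows(dataset, spec, names, row)
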