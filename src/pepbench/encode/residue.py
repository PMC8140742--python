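"""Per-residue (position-wise) encoders: one-hot, substitution-matrix row,
z-scales and single amino-acid index.

These encoders need every sequence to cover the same positions, so they
accept either equal-length (pre-aligned) input or a pluggable ``aligner``
hook — a callable mapping the list of raw sequences to a list of
equal-length aligned strings that may contain ``-`` gaps (e.g. a wrapper
around an external MUSCLE/MAFFT run).  There is no built-in aligner.
Gap columns encode as all-zero blocks.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from pepbench.datasets import AMINO_ACIDS, PeptideDataset
from pepbench.encode import tables
from pepbench.encode.base import EncodedDataset, EncodingSpec, register
from pepbench.errors import AlignmentRequiredError, InvalidIndexError

Aligner = Callable[[Sequence[str]], list[str]]


def _aligned_sequences(dataset: PeptideDataset, aligner: Aligner | None) -> list[str]:
    seqs = dataset.sequences
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        return list(seqs)
    if aligner is None:
        raise AlignmentRequiredError(
            f"ragged lengths {sorted(lengths)} and no aligner configured"
        )
    aligned = aligner(seqs)
    if len({len(s) for s in aligned}) != 1 or len(aligned) != len(seqs):
        raise AlignmentRequiredError("aligner returned ragged or mismatched output")
    return list(aligned)


def _per_position(
    dataset: PeptideDataset,
    spec: EncodingSpec,
    aligner: Aligner | None,
    block_names: list[str],
    block_of: dict[str, np.ndarray],
) -> EncodedDataset:
    aligned = _aligned_sequences(dataset, aligner)
    width = len(block_names)
    length = len(aligned[0])
    zero = np.zeros(width)
    names = [f"{spec.group}.p{p + 1}.{b}" for p in range(length) for b in block_names]
    matrix = np.vstack(
        [np.concatenate([block_of.get(a, zero) for a in seq]) for seq in aligned]
    )
    return EncodedDataset(spec, dataset.ids, names, matrix)


@register("binary")
def binary(
    dataset: PeptideDataset, aligner: Aligner | None = None, spec: EncodingSpec | None = None
) -> EncodedDataset:
    """One-hot encoding: 20 features per aligned position."""
    spec = spec or EncodingSpec("binary")
    blocks = {a: np.eye(20)[i] for i, a in enumerate(AMINO_ACIDS)}
    return _per_position(dataset, spec, aligner, list(AMINO_ACIDS), blocks)


@register("blosum62")
def blosum62(
    dataset: PeptideDataset, aligner: Aligner | None = None, spec: EncodingSpec | None = None
) -> EncodedDataset:
    """BLOSUM62 substitution-matrix row per aligned position (20 features/pos)."""
    spec = spec or EncodingSpec("blosum62")
    mat = substitution_matrices.load("BLOSUM62")
    blocks = {
        a: np.array([float(mat[a, b]) for b in AMINO_ACIDS]) for a in AMINO_ACIDS
    }
    return _per_position(dataset, spec, aligner, list(AMINO_ACIDS), blocks)


@register("zscale")
def zscale(
    dataset: PeptideDataset, aligner: Aligner | None = None, spec: EncodingSpec | None = None
) -> EncodedDataset:
    """Sandberg z-scale values per aligned position (5 features/pos)."""
    spec = spec or EncodingSpec("zscale")
    blocks = {a: np.asarray(tables.ZSCALES[a]) for a in AMINO_ACIDS}
    return _per_position(dataset, spec, aligner, [f"z{i}" for i in range(1, 6)], blocks)


@register("aaindex", {"index": lambda v: v in tables.AAINDEX_SUBSET}, {"index": "KYTJ820101"})
def aaindex(
    dataset: PeptideDataset,
    index: str = "KYTJ820101",
    aligner: Aligner | None = None,
    spec: EncodingSpec | None = None,
) -> EncodedDataset:
    """Single amino-acid index value per aligned position (1 feature/pos)."""
    spec = spec or EncodingSpec("aaindex", {"index": index})
    if index not in tables.AAINDEX_SUBSET:
        raise InvalidIndexError(f"unknown index {index!r}")
    scale = tables.AAINDEX_SUBSET[index]
    blocks = {a: np.array([scale[a]]) for a in AMINO_ACIDS}
    return _per_position(dataset, spec, aligner, [index], blocks)
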