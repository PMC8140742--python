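"""Conjoint-triad descriptors over the 7-class reduced alphabet.

ctriad counts residue-class triads at adjacent positions; ksctriad
additionally counts k-skipped triads (positions i, i+k+1, i+2k+2) for every
skip k up to kmax.  A skip of k requires sequence length >= 2k+3; shorter
records are dropped.  Each 343-feature block is min-max normalised.
"""

from __future__ import annotations

import numpy as np

from pepbench.datasets import PeptideDataset
from pepbench.encode import tables
from pepbench.encode.base import EncodedDataset, EncodingSpec, TooShort, encode_rows, register

_CLASSES = tables.CONJOINT_TRIAD_CLASSES
_CMAP = tables.group_index(_CLASSES)


def _triad_block(cs: list[int], skip: int) -> np.ndarray:
    """Min-max normalised counts of class triads (i, i+skip+1, i+2*skip+2)."""
    n = len(cs) - 2 * (skip + 1)
    if n < 1:
        raise TooShort(f"length {len(cs)} < {2 * skip + 3} required for skip {skip}")
    counts = np.zeros(343)
    for i in range(n):
        a, b, c = cs[i], cs[i + skip + 1], cs[i + 2 * (skip + 1)]
        counts[a * 49 + b * 7 + c] += 1
    lo, hi = counts.min(), counts.max()
    return (counts - lo) / (hi - lo) if hi > lo else counts


def _triad_names(prefix: str, skip: int) -> list[str]:
    return [f"{prefix}.k{skip}.{a}{b}{c}" for a in range(7) for b in range(7) for c in range(7)]


@register("ctriad")
def ctriad(dataset: PeptideDataset, spec: EncodingSpec | None = None) -> EncodedDataset:
    """Conjoint-triad frequencies (skip 0 only; 343 features)."""
    spec = spec or EncodingSpec("ctriad")
    return encode_rows(
        dataset,
        spec,
        _triad_names("ctriad", 0),
        lambda s: _triad_block([_CMAP[a] for a in s], 0),
    )


@register("ksctriad", {"kmax": lambda v: isinstance(v, int) and 0 <= v <= 5}, {"kmax": 1})
def ksctriad(
    dataset: PeptideDataset, kmax: int = 1, spec: EncodingSpec | None = None
) -> EncodedDataset:
    """k-skipped conjoint triads for every skip 0..kmax (343 features per skip)."""
    spec = spec or EncodingSpec("ksctriad", {"kmax": kmax})
    names = [n for k in range(kmax + 1) for n in _triad_names("ksctriad", k)]

    def row(s: str) -> np.ndarray:
        cs = [_CMAP[a] for a in s]
        return np.concatenate([_triad_block(cs, k) for k in range(kmax + 1)])

    return encode_rows(dataset, spec, names, row)
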