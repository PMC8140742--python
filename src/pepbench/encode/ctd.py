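"""Composition / transition / distribution (CTD) descriptors.

Each physicochemical property splits the alphabet into three classes.
Composition gives class fractions, transition gives normalised counts of
adjacent class changes, and distribution gives the sequence-relative
position (in percent) of the first / 25% / 50% / 75% / last occurrence of
each class.
"""

from __future__ import annotations

import math

import numpy as np

from pepbench.datasets import PeptideDataset
from pepbench.encode import tables
from pepbench.encode.base import EncodedDataset, EncodingSpec, TooShort, encode_rows, register

_DEFAULT = tables.CTD_PROPERTIES


def _class_seq(seq: str, classes: tuple[str, str, str]) -> list[int]:
    gmap = tables.group_index(classes)
    return [gmap[a] for a in seq]


def _composition(cs: list[int]) -> np.ndarray:
    counts = np.bincount(cs, minlength=3).astype(float)
    return counts / len(cs)


def _transition(cs: list[int]) -> np.ndarray:
    if len(cs) < 2:
        raise TooShort("transition needs length >= 2")
    pairs = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
    counts = np.zeros(3)
    for a, b in zip(cs, cs[1:]):
        if a != b:
            counts[pairs[(min(a, b), max(a, b))]] += 1
    return counts / (len(cs) - 1)


def _distribution(cs: list[int]) -> np.ndarray:
    """First/25/50/75/100% landmark positions of each class, as % of length.

    For a class occurring N times, the q-landmark is the position (1-based,
    relative to sequence length, x100) of occurrence number max(1, ceil(qN)).
    Absent classes contribute zeros.
    """
    length = len(cs)
    out = np.zeros(15)
    for cls in range(3):
        positions = [i + 1 for i, c in enumerate(cs) if c == cls]
        if not positions:
            continue
        n = len(positions)
        for qi, q in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
            k = max(1, math.ceil(q * n))
            out[cls * 5 + qi] = positions[k - 1] / length * 100.0
    return out


_PARTS = {"composition": (_composition, 3, ("c1", "c2", "c3")),
          "transition": (_transition, 3, ("t12", "t13", "t23")),
          "distribution": (_distribution, 15,
                           tuple(f"d{c}.{q}" for c in (1, 2, 3)
                                 for q in ("first", "25", "50", "75", "100")))}


def _make_ctd(name: str, part: str):
    fn, width, suffixes = _PARTS[part]

    def enc(dataset: PeptideDataset, spec: EncodingSpec | None = None) -> EncodedDataset:
        spec = spec or EncodingSpec(name)
        names = [f"{name}.{prop}.{s}" for prop in _DEFAULT for s in suffixes]

        def row(seq: str) -> np.ndarray:
            return np.concatenate([fn(_class_seq(seq, _DEFAULT[p])) for p in _DEFAULT])

        return encode_rows(dataset, spec, names, row)

    enc.__doc__ = f"CTD {part} over {len(_DEFAULT)} physicochemical properties ({name})."
    enc.__name__ = name
    return register(name)(enc)


ctdc = _make_ctd("ctdc", "composition")
ctdt = _make_ctd("ctdt", "transition")
ctdd = _make_ctd("ctdd", "distribution")

# re-exported for oracle tests that exercise a single property
composition_of = _composition
transition_of = _transition
distribution_of = _distribution
class_sequence = _class_seq
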