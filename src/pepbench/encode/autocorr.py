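"""Autocorrelation descriptors: Moran, Geary and normalised Moreau-Broto.

Each encoder maps a sequence to one value per (amino-acid index, lag d)
pair, d = 1..lag.  Index tables are z-standardised over their 20 values
before use; a zero-variance index is rejected.

With P the standardised index, x_i = P(a_i), x̄ the mean over the sequence
and L its length:

  Moreau-Broto (normalised):  AC(d) = (1/(L-d)) Σ_i x_i x_{i+d}
  Moran:   I(d) = [(1/(L-d)) Σ_i (x_i-x̄)(x_{i+d}-x̄)] / [(1/L) Σ_i (x_i-x̄)²]
  Geary:   C(d) = [(1/(2(L-d))) Σ_i (x_i-x_{i+d})²] / [(1/(L-1)) Σ_i (x_i-x̄)²]

Moran and Geary are undefined on a compositionally constant sequence
(zero within-sequence variance); those entries are set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pepbench.datasets import AMINO_ACIDS, PeptideDataset
from pepbench.encode import tables
from pepbench.encode.base import EncodedDataset, EncodingSpec, TooShort, encode_rows, register
from pepbench.errors import InvalidIndexError


@dataclass(frozen=True)
class IndexTable:
    """A named 20-valued amino-acid scale."""

    identifier: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise InvalidIndexError(f"{self.identifier}: needs exactly 20 values")

    @classmethod
    def from_mapping(cls, identifier: str, mapping: dict[str, float]) -> "IndexTable":
        return cls(identifier, tuple(float(mapping[a]) for a in AMINO_ACIDS))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def variance(self) -> float:
        return float(np.var(self.as_array()))

    def standardized(self) -> np.ndarray:
        """Zero-mean, unit-variance version of the 20 values (population moments)."""
        v = self.as_array()
        sd = v.std()
        if sd == 0:
            raise InvalidIndexError(f"{self.identifier}: zero variance, unusable")
        return (v - v.mean()) / sd


def default_indices() -> list[IndexTable]:
    """The bundled AAindex-style subset as IndexTable objects."""
    return [
        IndexTable.from_mapping(name, vals) for name, vals in tables.AAINDEX_SUBSET.items()
    ]


def _resolve_indices(indices) -> list[IndexTable]:
    if indices is None:
        return default_indices()
    out = []
    for ix in indices:
        if isinstance(ix, IndexTable):
            out.append(ix)
        elif isinstance(ix, str):
            out.append(IndexTable.from_mapping(ix, tables.AAINDEX_SUBSET[ix]))
        else:
            raise InvalidIndexError(f"cannot interpret index {ix!r}")
    return out


def _autocorr_row(seq: str, std_values: np.ndarray, lag: int, variant: str) -> np.ndarray:
    if len(seq) <= lag:
        raise TooShort(f"length {len(seq)} <= lag {lag}")
    x = std_values[[AMINO_ACIDS.index(a) for a in seq]]
    L = len(x)
    out = np.empty(lag)
    if variant == "nmbroto":
        for d in range(1, lag + 1):
            out[d - 1] = np.dot(x[:-d], x[d:]) / (L - d)
        return out
    if np.ptp(x) == 0:  # constant profile: within-sequence variance is zero
        return np.zeros(lag)
    xbar = x.mean()
    dev = x - xbar
    if variant == "moran":
        denom = np.dot(dev, dev) / L
        for d in range(1, lag + 1):
            num = np.dot(dev[:-d], dev[d:]) / (L - d)
            out[d - 1] = num / denom if denom > 0 else 0.0
    elif variant == "geary":
        denom = np.dot(dev, dev) / (L - 1) if L > 1 else 0.0
        for d in range(1, lag + 1):
            num = np.sum((x[:-d] - x[d:]) ** 2) / (2 * (L - d))
            out[d - 1] = num / denom if denom > 0 else 0.0
    else:  # pragma: no cover
        raise ValueError(variant)
    return out


def _make_autocorr(name: str):
    def enc(
        dataset: PeptideDataset,
        lag: int = 2,
        indices=None,
        spec: EncodingSpec | None = None,
    ) -> EncodedDataset:
        spec = spec or EncodingSpec(name, {"lag": lag})
        idx = _resolve_indices(indices)
        std = [(t.identifier, t.standardized()) for t in idx]
        names = [f"{name}.{ident}.d{d}" for ident, _ in std for d in range(1, lag + 1)]

        def row(s: str) -> np.ndarray:
            return np.concatenate([_autocorr_row(s, sv, lag, name) for _, sv in std])

        return encode_rows(dataset, spec, names, row)

    enc.__doc__ = f"{name} autocorrelation per standardised index per lag."
    enc.__name__ = name
    return register(
        name, {"lag": lambda v: isinstance(v, int) and 1 <= v <= 30}, {"lag": 2}
    )(enc)


moran = _make_autocorr("moran")
geary = _make_autocorr("geary")
nmbroto = _make_autocorr("nmbroto")
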