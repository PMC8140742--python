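"""Sequence-order and pseudo amino-acid composition descriptors.

socnumber/qsorder build on sequence-order coupling numbers
tau_d = Σ_i dist(a_i, a_{i+d})² computed with two bundled 20x20 residue
distance matrices (a reconstructed physicochemical matrix and the Grantham
distance).  paac/apaac follow Chou's pseudo amino-acid composition with
the classic hydrophobicity / hydrophilicity / side-chain-mass scales,
standardised over the 20 residues.
"""

from __future__ import annotations

import numpy as np

from pepbench.datasets import AMINO_ACIDS, PeptideDataset
from pepbench.encode import tables
from pepbench.encode.base import EncodedDataset, EncodingSpec, TooShort, encode_rows, register

_MATRICES = tables.ORDER_DISTANCE_MATRICES


def _coupling_numbers(codes: list[int], dist: np.ndarray, nlag: int) -> np.ndarray:
    """tau_d = sum over i of dist(a_i, a_{i+d})^2, for d = 1..nlag."""
    L = len(codes)
    if L <= nlag:
        raise TooShort(f"length {L} <= nlag {nlag}")
    taus = np.empty(nlag)
    for d in range(1, nlag + 1):
        taus[d - 1] = sum(dist[codes[i], codes[i + d]] ** 2 for i in range(L - d))
    return taus


@register(
    "socnumber",
    {"nlag": lambda v: isinstance(v, int) and 1 <= v <= 30},
    {"nlag": 2},
)
def socnumber(
    dataset: PeptideDataset, nlag: int = 2, spec: EncodingSpec | None = None
) -> EncodedDataset:
    """Sequence-order coupling numbers tau_1..tau_nlag for each distance matrix."""
    spec = spec or EncodingSpec("socnumber", {"nlag": nlag})
    names = [f"soc.{m}.d{d}" for m in _MATRICES for d in range(1, nlag + 1)]

    def row(s: str) -> np.ndarray:
        codes = [AMINO_ACIDS.index(a) for a in s]
        return np.concatenate(
            [_coupling_numbers(codes, dist, nlag) for dist in _MATRICES.values()]
        )

    return encode_rows(dataset, spec, names, row)


@register(
    "qsorder",
    {
        "nlag": lambda v: isinstance(v, int) and 1 <= v <= 30,
        "weight": lambda v: isinstance(v, (int, float)) and v > 0,
    },
    {"nlag": 2, "weight": 0.1},
)
def qsorder(
    dataset: PeptideDataset,
    nlag: int = 2,
    weight: float = 0.1,
    spec: EncodingSpec | None = None,
) -> EncodedDataset:
    """Quasi-sequence-order descriptors.

    Per distance matrix: 20 composition features f_a / (Σf + w Σtau)
    followed by nlag order features w tau_d / (Σf + w Σtau).
    """
    spec = spec or EncodingSpec("qsorder", {"nlag": nlag, "weight": weight})
    names = [
        f"qso.{m}.{x}"
        for m in _MATRICES
        for x in list(AMINO_ACIDS) + [f"d{d}" for d in range(1, nlag + 1)]
    ]

    def row(s: str) -> np.ndarray:
        codes = [AMINO_ACIDS.index(a) for a in s]
        freqs = np.bincount(codes, minlength=20).astype(float)
        blocks = []
        for dist in _MATRICES.values():
            taus = _coupling_numbers(codes, dist, nlag)
            denom = freqs.sum() + weight * taus.sum()
            blocks.append(np.concatenate([freqs / denom, weight * taus / denom]))
        return np.concatenate(blocks)

    return encode_rows(dataset, spec, names, row)


def _standardized_scales(mappings: list[dict[str, float]]) -> np.ndarray:
    """Stack scales as rows, z-standardised over the 20 residues (population sd)."""
    rows = []
    for m in mappings:
        v = np.array([m[a] for a in AMINO_ACIDS])
        rows.append((v - v.mean()) / v.std())
    return np.vstack(rows)


_PAAC_SCALES = _standardized_scales(
    [tables.HYDROPHOBICITY, tables.HYDROPHILICITY, tables.SIDE_CHAIN_MASS]
)
_APAAC_SCALES = _standardized_scales([tables.HYDROPHOBICITY, tables.HYDROPHILICITY])


@register(
    "paac",
    {
        "lam": lambda v: isinstance(v, int) and 1 <= v <= 30,
        "weight": lambda v: isinstance(v, (int, float)) and v >= 0,
    },
    {"lam": 2, "weight": 0.05},
)
def paac(
    dataset: PeptideDataset,
    lam: int = 2,
    weight: float = 0.05,
    spec: EncodingSpec | None = None,
) -> EncodedDataset:
    """Chou's pseudo amino-acid composition (20 + lam features, sums to 1).

    theta_d averages Theta(a_i, a_{i+d}) = mean over the three standardised
    scales of (P(a_{i+d}) - P(a_i))² over all i.
    """
    spec = spec or EncodingSpec("paac", {"lam": lam, "weight": weight})
    names = [f"paac.{a}" for a in AMINO_ACIDS] + [f"paac.lam{d}" for d in range(1, lam + 1)]

    def row(s: str) -> np.ndarray:
        L = len(s)
        if L <= lam:
            raise TooShort(f"length {L} <= lambda {lam}")
        codes = [AMINO_ACIDS.index(a) for a in s]
        freqs = np.bincount(codes, minlength=20).astype(float) / L
        thetas = np.empty(lam)
        for d in range(1, lam + 1):
            vals = [
                np.mean((_PAAC_SCALES[:, codes[i + d]] - _PAAC_SCALES[:, codes[i]]) ** 2)
                for i in range(L - d)
            ]
            thetas[d - 1] = np.mean(vals)
        denom = freqs.sum() + weight * thetas.sum()
        return np.concatenate([freqs / denom, weight * thetas / denom])

    return encode_rows(dataset, spec, names, row)


@register(
    "apaac",
    {
        "lam": lambda v: isinstance(v, int) and 1 <= v <= 30,
        "weight": lambda v: isinstance(v, (int, float)) and v >= 0,
    },
    {"lam": 2, "weight": 0.05},
)
def apaac(
    dataset: PeptideDataset,
    lam: int = 2,
    weight: float = 0.05,
    spec: EncodingSpec | None = None,
) -> EncodedDataset:
    """Amphiphilic pseudo amino-acid composition (20 + 2*lam features, sums to 1).

    The lag block holds, for each d, the hydrophobicity and hydrophilicity
    cross-correlations tau = (1/(L-d)) Σ_i P(a_i) P(a_{i+d}).
    """
    spec = spec or EncodingSpec("apaac", {"lam": lam, "weight": weight})
    names = [f"apaac.{a}" for a in AMINO_ACIDS] + [
        f"apaac.lam{d}.{p}" for d in range(1, lam + 1) for p in ("h1", "h2")
    ]

    def row(s: str) -> np.ndarray:
        L = len(s)
        if L <= lam:
            raise TooShort(f"length {L} <= lambda {lam}")
        codes = [AMINO_ACIDS.index(a) for a in s]
        freqs = np.bincount(codes, minlength=20).astype(float) / L
        taus = []
        for d in range(1, lam + 1):
            for p in range(2):
                vals = _APAAC_SCALES[p]
                taus.append(
                    np.mean([vals[codes[i]] * vals[codes[i + d]] for i in range(L - d)])
                )
        taus = np.asarray(taus)
        denom = freqs.sum() + weight * taus.sum()
        if denom <= 0:
            raise TooShort("degenerate apaac normaliser (non-positive)")
        return np.concatenate([freqs / denom, weight * taus / denom])

    return encode_rows(dataset, spec, names, row)
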