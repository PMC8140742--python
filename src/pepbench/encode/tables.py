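"""Bundled physicochemical data assets used by the encoders.

All tables are keyed by one-letter amino-acid code over the 20 natural
amino acids.  Provenance of each block is stated in a comment; the
Schneider–Wrede-style distance matrix is a reconstruction (see its note).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# 5-group physicochemical partition (aliphatic / aromatic / positive /
# negative / uncharged), as used by grouped composition descriptors (GAAC
# family) in the descriptor literature.
FIVE_GROUPS: dict[str, str] = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}

# 7-class reduced alphabet of the conjoint-triad descriptor (Shen et al.,
# classes grouped by dipole and side-chain volume).
CONJOINT_TRIAD_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

# 4-class reduction used by the chaos-game encoder: hydrophobic / polar /
# positively charged / negatively charged side chains (package default; the
# partition is configurable).
FCGR_CLASSES: tuple[str, ...] = ("AVLIMFW", "STNQYCGP", "KRH", "DE")

# ---------------------------------------------------------------------------
# CTD property partitions (Dubchak et al. three-class attribute groupings,
# as popularised by PROFEAT-style descriptor suites).  Each property splits
# the alphabet into three classes.
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

# ---------------------------------------------------------------------------
# Sandberg et al. (1998) z-scales: five orthogonal principal-property
# scores per amino acid (z1 lipophilicity, z2 steric bulk/polarizability,
# z3 polarity, z4/z5 electronic effects).
ZSCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

# ---------------------------------------------------------------------------
# Pseudo amino-acid composition property scales (the three classic ones:
# Eisenberg-consensus hydrophobicity, Hopp-Woods hydrophilicity and
# side-chain mass in Dalton).
HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}
HYDROPHILICITY: dict[str, float] = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
    "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
    "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
    "Y": -2.3, "V": -1.5,
}
SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0, "Q": 72.0,
    "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0, "L": 57.0, "K": 73.0,
    "M": 75.0, "F": 91.0, "P": 42.0, "S": 31.0, "T": 45.0, "W": 130.0,
    "Y": 107.0, "V": 43.0,
}

# ---------------------------------------------------------------------------
# Bundled AAindex-style subset: a handful of classic 20-valued scales,
# enough for the index-based encoders and the index-redundancy filter.
AAINDEX_SUBSET: dict[str, dict[str, float]] = {
    # Kyte & Doolittle hydropathy
    "KYTJ820101": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    },
    # Hopp & Woods hydrophilicity
    "HOPT810101": dict(HYDROPHILICITY),
    # Grantham polarity
    "GRAR740102": {
        "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
        "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
        "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
        "Y": 6.2, "V": 5.9,
    },
    # Residue molecular weight
    "FASG760101": {
        "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.15,
        "Q": 146.15, "E": 147.13, "G": 75.07, "H": 155.16, "I": 131.17,
        "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
        "S": 105.09, "T": 119.12, "W": 204.24, "Y": 181.19, "V": 117.15,
    },
    # Isoelectric point
    "ZIMJ680104": {
        "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.05, "Q": 5.65,
        "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
        "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.66, "W": 5.89,
        "Y": 5.66, "V": 5.96,
    },
    # Eisenberg consensus hydrophobicity
    "EISD840101": dict(HYDROPHOBICITY),
}

# ---------------------------------------------------------------------------
# Grantham (1974) amino-acid difference properties: composition (c),
# polarity (p) and molecular volume (v).  The pairwise Grantham distance is
# recomputed from these with the published constants, rather than storing
# the 20x20 matrix.
_GRANTHAM_PROPS: dict[str, tuple[float, float, float]] = {
    # aa: (composition, polarity, volume)
    "S": (1.42, 9.2, 32.0), "R": (0.65, 10.5, 124.0), "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61.0), "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0), "G": (0.74, 9.0, 3.0), "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0), "Y": (0.20, 6.2, 136.0), "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0), "Q": (0.89, 10.5, 85.0), "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0), "D": (1.38, 13.0, 54.0), "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0), "W": (0.13, 5.4, 170.0),
}


def _grantham_matrix() -> np.ndarray:
    """20x20 Grantham distance, D = 50.723 * sqrt(1.833 dc^2 + 0.1018 dp^2 + 0.000399 dv^2)."""
    mat = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        ca, pa, va = _GRANTHAM_PROPS[a]
        for j, b in enumerate(AMINO_ACIDS):
            cb, pb, vb = _GRANTHAM_PROPS[b]
            mat[i, j] = 50.723 * np.sqrt(
                1.833 * (ca - cb) ** 2 + 0.1018 * (pa - pb) ** 2 + 0.000399 * (va - vb) ** 2
            )
    return mat


def _physchem_distance_matrix() -> np.ndarray:
    """Hydrophobicity/volume dissimilarity in the style of Schneider & Wrede.

    NOTE: this matrix is a reconstruction, not a copy of the originally
    published table: the pairwise distance is the euclidean combination of
    range-normalised hydrophobicity and side-chain-volume differences,
    scaled to [0, 1].  It preserves the qualitative structure (zero
    diagonal, symmetric, conservative substitutions close) that the
    sequence-order descriptors rely on.
    """
    h = np.array([HYDROPHOBICITY[a] for a in AMINO_ACIDS])
    v = np.array([_GRANTHAM_PROPS[a][2] for a in AMINO_ACIDS])
    h = (h - h.min()) / (h.max() - h.min())
    v = (v - v.min()) / (v.max() - v.min())
    dh = h[:, None] - h[None, :]
    dv = v[:, None] - v[None, :]
    return np.sqrt((dh**2 + dv**2) / 2.0)


GRANTHAM_DISTANCE: np.ndarray = _grantham_matrix()
PHYSCHEM_DISTANCE: np.ndarray = _physchem_distance_matrix()

#: Distance matrices used by the sequence-order encoders, in block order.
ORDER_DISTANCE_MATRICES: dict[str, np.ndarray] = {
    "physchem": PHYSCHEM_DISTANCE,
    "grantham": GRANTHAM_DISTANCE,
}

# ---------------------------------------------------------------------------
# Reduced-alphabet families for the pseudo K-tuple reduced amino-acid
# composition.  One conservative family is bundled ("type1",
# hydrophobicity-ordered nested clusters); clusters=20 is the identity
# reduction.
PSEKRAAC_FAMILIES: dict[str, dict[int, tuple[str, ...]]] = {
    "type1": {
        2: ("CMFILVWY", "AGTSNQDEHRKP"),
        3: ("CMFILVWY", "AGTSP", "NQDEHRK"),
        4: ("CMFWY", "ILV", "AGTS", "NQDEHRKP"),
        5: ("WFYH", "MILV", "CATSP", "G", "NQDERK"),
        8: ("WFYH", "MILV", "CA", "NTS", "P", "G", "DE", "QRK"),
        10: ("WFY", "ML", "IV", "CA", "TS", "NH", "P", "G", "DE", "QRK"),
        15: ("WFY", "ML", "IV", "C", "A", "T", "S", "N", "H", "P", "G", "D", "E", "Q", "RK"),
        20: tuple(AMINO_ACIDS),
    },
}


def group_index(groups: tuple[str, ...] | dict[str, str]) -> dict[str, int]:
    """Map each amino acid to the 0-based index of its class in ``groups``."""
    seqs = list(groups.values()) if isinstance(groups, dict) else list(groups)
    out: dict[str, int] = {}
    for k, members in enumerate(seqs):
        for aa in members:
            out[aa] = k
    missing = set(AMINO_ACIDS) - set(out)
    if missing:
        raise ValueError(f"partition does not cover {sorted(missing)}")
    return out
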