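"""Independent brute-force reference implementations for the encoders and
statistics.

Each oracle is a short, direct transcription of the descriptor's textbook
definition (explicit loops, dictionaries, the statistics module), kept
deliberately separate from the package's vectorised implementations.
Feature order follows the documented layout of the corresponding encoder.
"""

from __future__ import annotations

import math
import statistics
from itertools import product

from pepbench.encode import tables

AA = "ACDEFGHIKLMNPQRSTVWY"
FIVE = list(tables.FIVE_GROUPS.values())
TRIAD7 = list(tables.CONJOINT_TRIAD_CLASSES)
FCGR4 = list(tables.FCGR_CLASSES)


def _class_of(aa: str, classes) -> int:
    for i, members in enumerate(classes):
        if aa in members:
            return i
    raise KeyError(aa)


# --- compositional ---------------------------------------------------------

def kmer_freqs(seq: str, k: int, alphabet=None, classes=None) -> list[float] | None:
    """Overlapping k-mer frequencies in product order; None if too short."""
    if classes is not None:
        symbols = [str(_class_of(a, classes)) for a in seq]
        letters = [str(i) for i in range(len(classes))]
    else:
        symbols = list(seq)
        letters = list(alphabet or AA)
    n = len(symbols) - k + 1
    if n < 1:
        return None
    counts: dict[tuple, int] = {}
    for i in range(n):
        key = tuple(symbols[i : i + k])
        counts[key] = counts.get(key, 0) + 1
    return [counts.get(t, 0) / n for t in product(letters, repeat=k)]


def cksaap(seq: str, gmax: int, classes=None) -> list[float] | None:
    if classes is not None:
        symbols = [str(_class_of(a, classes)) for a in seq]
        letters = [str(i) for i in range(len(classes))]
    else:
        symbols, letters = list(seq), list(AA)
    out: list[float] = []
    for g in range(gmax + 1):
        pairs = [(symbols[i], symbols[i + g + 1]) for i in range(len(symbols) - g - 1)]
        if not pairs:
            return None
        for a in letters:
            for b in letters:
                out.append(pairs.count((a, b)) / len(pairs))
    return out


def sliding_composition(seq: str, window: int, classes=None) -> list[float] | None:
    if len(seq) < window:
        return None
    if classes is not None:
        letters = [str(i) for i in range(len(classes))]
        symbols = [str(_class_of(a, classes)) for a in seq]
    else:
        letters, symbols = list(AA), list(seq)
    out = []
    for start in range(len(seq) - window + 1):
        chunk = symbols[start : start + window]
        out.extend(chunk.count(a) / window for a in letters)
    return out


def distance_frequency(seq: str, bins: int) -> list[float]:
    out = []
    L = len(seq)
    for a in AA:
        counts = [0] * bins
        for i, c in enumerate(seq):
            if c == a:
                pos = 0.0 if L == 1 else i / (L - 1)
                counts[min(int(pos * bins), bins - 1)] += 1
        out.extend(c / L for c in counts)
    return out


# --- autocorrelation -------------------------------------------------------

def _standardize20(values: dict[str, float]) -> dict[str, float]:
    mean = statistics.fmean(values[a] for a in AA)
    sd = statistics.pstdev(values[a] for a in AA)
    return {a: (values[a] - mean) / sd for a in AA}


def autocorrelation(seq: str, index: dict[str, float], lag: int, variant: str) -> list[float] | None:
    if len(seq) <= lag:
        return None
    p = _standardize20(index)
    x = [p[a] for a in seq]
    L = len(x)
    xbar = statistics.fmean(x)
    constant = max(x) == min(x)
    out = []
    for d in range(1, lag + 1):
        if variant == "nmbroto":
            out.append(sum(x[i] * x[i + d] for i in range(L - d)) / (L - d))
        elif constant:  # moran/geary undefined on a constant profile
            out.append(0.0)
        elif variant == "moran":
            denom = sum((v - xbar) ** 2 for v in x) / L
            num = sum((x[i] - xbar) * (x[i + d] - xbar) for i in range(L - d)) / (L - d)
            out.append(num / denom if denom > 0 else 0.0)
        elif variant == "geary":
            denom = sum((v - xbar) ** 2 for v in x) / (L - 1)
            num = sum((x[i] - x[i + d]) ** 2 for i in range(L - d)) / (2 * (L - d))
            out.append(num / denom if denom > 0 else 0.0)
    return out


# --- CTD -------------------------------------------------------------------

def ctd_composition(seq: str, classes3) -> list[float]:
    cs = [_class_of(a, classes3) for a in seq]
    return [cs.count(k) / len(cs) for k in range(3)]


def ctd_transition(seq: str, classes3) -> list[float] | None:
    cs = [_class_of(a, classes3) for a in seq]
    if len(cs) < 2:
        return None
    out = []
    for r, s in ((0, 1), (0, 2), (1, 2)):
        n = sum(
            1
            for i in range(len(cs) - 1)
            if {cs[i], cs[i + 1]} == {r, s}
        )
        out.append(n / (len(cs) - 1))
    return out


def ctd_distribution(seq: str, classes3) -> list[float]:
    cs = [_class_of(a, classes3) for a in seq]
    out = []
    for k in range(3):
        pos = [i + 1 for i, c in enumerate(cs) if c == k]
        for q in (0.0, 0.25, 0.5, 0.75, 1.0):
            if not pos:
                out.append(0.0)
            else:
                idx = max(1, math.ceil(q * len(pos)))
                out.append(pos[idx - 1] / len(cs) * 100.0)
    return out


# --- conjoint triads -------------------------------------------------------

def triad_block(seq: str, skip: int) -> list[float] | None:
    cs = [_class_of(a, TRIAD7) for a in seq]
    n = len(cs) - 2 * (skip + 1)
    if n < 1:
        return None
    counts: dict[tuple, int] = {}
    for i in range(n):
        key = (cs[i], cs[i + skip + 1], cs[i + 2 * (skip + 1)])
        counts[key] = counts.get(key, 0) + 1
    raw = [counts.get((a, b, c), 0) for a in range(7) for b in range(7) for c in range(7)]
    lo, hi = min(raw), max(raw)
    return [(v - lo) / (hi - lo) if hi > lo else float(v) for v in raw]


# --- sequence order / pseudo composition -----------------------------------

def coupling(seq: str, dist, nlag: int) -> list[float] | None:
    if len(seq) <= nlag:
        return None
    out = []
    for d in range(1, nlag + 1):
        out.append(
            sum(dist[AA.index(seq[i]), AA.index(seq[i + d])] ** 2 for i in range(len(seq) - d))
        )
    return out


def qsorder(seq: str, nlag: int, weight: float) -> list[float] | None:
    out = []
    for dist in tables.ORDER_DISTANCE_MATRICES.values():
        taus = coupling(seq, dist, nlag)
        if taus is None:
            return None
        denom = len(seq) + weight * sum(taus)
        out.extend(seq.count(a) / denom for a in AA)
        out.extend(weight * t / denom for t in taus)
    return out


def paac(seq: str, lam: int, weight: float) -> list[float] | None:
    if len(seq) <= lam:
        return None
    scales = [
        _standardize20(tables.HYDROPHOBICITY),
        _standardize20(tables.HYDROPHILICITY),
        _standardize20(tables.SIDE_CHAIN_MASS),
    ]
    L = len(seq)
    thetas = []
    for d in range(1, lam + 1):
        vals = []
        for i in range(L - d):
            vals.append(statistics.fmean((s[seq[i + d]] - s[seq[i]]) ** 2 for s in scales))
        thetas.append(statistics.fmean(vals))
    denom = 1.0 + weight * sum(thetas)  # frequencies already sum to 1
    out = [seq.count(a) / L / denom for a in AA]
    out.extend(weight * t / denom for t in thetas)
    return out


def apaac(seq: str, lam: int, weight: float) -> list[float] | None:
    if len(seq) <= lam:
        return None
    scales = [_standardize20(tables.HYDROPHOBICITY), _standardize20(tables.HYDROPHILICITY)]
    L = len(seq)
    taus = []
    for d in range(1, lam + 1):
        for s in scales:
            taus.append(statistics.fmean(s[seq[i]] * s[seq[i + d]] for i in range(L - d)))
    denom = 1.0 + weight * sum(taus)
    if denom <= 0:
        return None
    out = [seq.count(a) / L / denom for a in AA]
    out.extend(weight * t / denom for t in taus)
    return out


# --- reduced alphabet ------------------------------------------------------

def psekraac(seq: str, classes, ktuple: int, gap: int) -> list[float] | None:
    cs = [_class_of(a, classes) for a in seq]
    span = (ktuple - 1) * (gap + 1) + 1
    n = len(cs) - span + 1
    if n < 1:
        return None
    counts: dict[tuple, int] = {}
    for i in range(n):
        key = tuple(cs[i + j * (gap + 1)] for j in range(ktuple))
        counts[key] = counts.get(key, 0) + 1
    return [counts.get(t, 0) / n for t in product(range(len(classes)), repeat=ktuple)]


# --- per-residue -----------------------------------------------------------

def one_hot(seq: str) -> list[float]:
    out = []
    for a in seq:
        out.extend(1.0 if a == b else 0.0 for b in AA)
    return out


def zscale(seq: str) -> list[float]:
    out = []
    for a in seq:
        out.extend(tables.ZSCALES[a])
    return out


def aaindex_profile(seq: str, index: str) -> list[float]:
    scale = tables.AAINDEX_SUBSET[index]
    return [scale[a] for a in seq]


# --- chaos game ------------------------------------------------------------

def fcgr(seq: str, resolution: int) -> list[float]:
    corners = {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (0.0, 1.0), 3: (1.0, 1.0)}
    grid = [[0.0] * resolution for _ in range(resolution)]
    x = y = 0.5
    for a in seq:
        cx, cy = corners[_class_of(a, FCGR4)]
        x, y = (x + cx) / 2, (y + cy) / 2
        col = min(int(x * resolution), resolution - 1)
        row = min(int(y * resolution), resolution - 1)
        grid[row][col] += 1
    return [v / len(seq) for row in grid for v in row]


# --- statistics ------------------------------------------------------------

def pearson(x, y) -> float:
    n = len(x)
    mx, my = statistics.fmean(x), statistics.fmean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def adjusted_r2(x, y) -> float:
    n = len(x)
    return 1 - (n - 1) / (n - 2) * (1 - pearson(x, y) ** 2)


def rv_adjusted(X, Y) -> float:
    """Double-loop evaluation over columns of two row-major nested lists."""
    p, q = len(X[0]), len(Y[0])
    col = lambda M, j: [row[j] for row in M]  # noqa: E731
    num = sum(adjusted_r2(col(X, i), col(Y, j)) for i in range(p) for j in range(q))
    dx = sum(adjusted_r2(col(X, i), col(X, j)) for i in range(p) for j in range(p))
    dy = sum(adjusted_r2(col(Y, i), col(Y, j)) for i in range(q) for j in range(q))
    return num / math.sqrt(dx * dy)


def friedman(ranks) -> float:
    n, k = len(ranks), len(ranks[0])
    avg = [statistics.fmean(col) for col in zip(*ranks)]
    return 12 * n / (k * (k + 1)) * (sum(r**2 for r in avg) - k * (k + 1) ** 2 / 4)
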