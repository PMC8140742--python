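"""Statistical comparison layer for benchmarked encodings.

Covers classifier-output similarity (disagreement, Phi), the Friedman
rank test with the Iman-Davenport correction and the Nemenyi critical
difference, adjusted-Pearson / adjusted-RV matrix correlation between
encoded datasets, Davies-Bouldin class-separation scoring, and
cross-dataset group ranking with UPGMA clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from pepbench.errors import InvalidParameterError, UndefinedStatisticError

# ---------------------------------------------------------------------------
# classifier-output similarity


def disagreement(o_i: Sequence[int], o_j: Sequence[int]) -> float:
    """Fraction of cases on which two binary classifier outputs differ.

    D = (1/n) * sum_k |o_i[k] - o_j[k]|; 0 for identical outputs, 1 for
    complementary ones.
    """
    a = np.asarray(o_i, dtype=float)
    b = np.asarray(o_j, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise InvalidParameterError("disagreement needs two equal-length non-empty vectors")
    return float(np.mean(np.abs(a - b)))


def phi_coefficient(o_i: Sequence[int], o_j: Sequence[int]) -> float:
    """Phi (2x2 Pearson) coefficient of two binary output vectors.

    With the contingency counts a=both 1, b=i only, c=j only, d=both 0:
    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).  Undefined (raises) when
    either vector is constant.
    """
    x = np.asarray(o_i, dtype=int)
    y = np.asarray(o_j, dtype=int)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise InvalidParameterError("phi needs two equal-length non-empty vectors")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise UndefinedStatisticError("phi undefined: a constant output vector")
    return float((a * d - b * c) / np.sqrt(denom))


@dataclass
class SimilarityMatrix:
    """Symmetric model-pair similarity with a measure tag."""

    labels: list[str]
    values: np.ndarray
    measure: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_similarity(cv_results, measure: str = "disagreement") -> SimilarityMatrix:
    """Average per-fold similarity between all pairs of paired CV results.

    All results must share fold partitions (use the paired two-group CV),
    so the k-th row of each result covers the same test records.  The
    measure is computed per fold row on the predicted class vectors and
    averaged over rows; fold rows where Phi is undefined (a constant
    prediction vector) are skipped in the average for that pair.
    """
    funcs = {"disagreement": disagreement, "phi": phi_coefficient}
    if measure not in funcs:
        raise InvalidParameterError(f"unknown similarity measure {measure!r}")
    fn = funcs[measure]
    results = list(cv_results)
    if len(results) < 2:
        raise InvalidParameterError("need at least two CV results")
    n_rows = {len(r.rows) for r in results}
    if len(n_rows) != 1:
        raise InvalidParameterError("unpaired CV results: differing fold-row counts")
    for r in results[1:]:
        for row_a, row_b in zip(results[0].rows, r.rows):
            if row_a.ids != row_b.ids:
                raise InvalidParameterError("unpaired CV results: fold record ids differ")
    k = len(results)
    labels = [r.spec.id for r in results]
    out = np.zeros((k, k))
    if measure == "phi":
        np.fill_diagonal(out, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            vals = []
            for row_i, row_j in zip(results[i].rows, results[j].rows):
                try:
                    vals.append(fn(row_i.y_pred, row_j.y_pred))
                except UndefinedStatisticError:
                    continue
            if not vals:
                raise UndefinedStatisticError(
                    f"{measure} undefined on every fold for pair ({labels[i]}, {labels[j]})"
                )
            out[i, j] = out[j, i] = float(np.mean(vals))
    return SimilarityMatrix(labels, out, measure)


# ---------------------------------------------------------------------------
# Friedman / Iman-Davenport / Nemenyi


@dataclass
class RankMatrix:
    """Per-fold ranks of k models over N folds (rank 1 = best, ties averaged)."""

    ranks: np.ndarray  # shape (N, k)
    labels: list[str]

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if self.ranks.ndim != 2:
            raise InvalidParameterError("ranks must be a 2-D fold x model array")
        n, k = self.ranks.shape
        expected = k * (k + 1) / 2
        if not np.allclose(self.ranks.sum(axis=1), expected):
            raise InvalidParameterError("each fold's ranks must sum to k(k+1)/2")

    @property
    def n_folds(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_models(self) -> int:
        return self.ranks.shape[1]

    @property
    def average_ranks(self) -> np.ndarray:
        """R_j = mean over folds of the j-th model's rank."""
        return self.ranks.mean(axis=0)


def rank_matrix_from_scores(scores: np.ndarray, labels: Sequence[str]) -> RankMatrix:
    """Rank models within each fold row of a (folds x models) score array.

    Rank 1 goes to the highest score; ties receive average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    ranks = np.vstack([sps.rankdata(-row, method="average") for row in scores])
    return RankMatrix(ranks, list(labels))


def friedman_statistic(rm: RankMatrix) -> float:
    """Friedman chi-square over N folds and k models:
    (12N / (k(k+1))) * [sum_j R_j^2 - k(k+1)^2 / 4].
    """
    n, k = rm.n_folds, rm.n_models
    if n < 2 or k < 2:
        raise InvalidParameterError(f"need N >= 2 folds and k >= 2 models, got {n}x{k}")
    r = rm.average_ranks
    return float(12.0 * n / (k * (k + 1)) * (np.sum(r**2) - k * (k + 1) ** 2 / 4.0))


def iman_davenport(chi2: float, n_folds: int, k_models: int) -> tuple[float, float]:
    """Iman-Davenport F-transform of the Friedman chi-square.

    F = ((N-1) chi2) / (N(k-1) - chi2), F-distributed with (k-1) and
    (k-1)(N-1) degrees of freedom.  Returns (F, p-value); raises when the
    denominator is non-positive (chi-square at its ceiling).
    """
    denom = n_folds * (k_models - 1) - chi2
    if denom <= 0:
        raise UndefinedStatisticError(
            f"Iman-Davenport degenerate: chi2={chi2} reaches N(k-1)={n_folds * (k_models - 1)}"
        )
    f_value = (n_folds - 1) * chi2 / denom
    df1 = k_models - 1
    df2 = (k_models - 1) * (n_folds - 1)
    p = float(sps.f.sf(f_value, df1, df2))
    return float(f_value), p


def nemenyi_q(k_models: int, alpha: float = 0.05) -> float:
    """Critical value q_alpha = (Studentized range quantile at infinite df) / sqrt(2)."""
    if k_models < 2:
        raise InvalidParameterError("need k >= 2 models")
    if alpha not in (0.05, 0.10):
        raise InvalidParameterError("alpha must be 0.05 or 0.10")
    return float(sps.studentized_range.ppf(1.0 - alpha, k_models, np.inf) / np.sqrt(2.0))


def nemenyi_cd(k_models: int, n_folds: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference CD = q_alpha * sqrt(k(k+1) / (6N)).

    Two models differ significantly when their average ranks differ by at
    least CD.
    """
    if n_folds < 1:
        raise InvalidParameterError("need N >= 1 folds")
    return nemenyi_q(k_models, alpha) * float(np.sqrt(k_models * (k_models + 1) / (6.0 * n_folds)))


def significant_pairs(rm: RankMatrix, alpha: float = 0.05) -> list[tuple[str, str, float]]:
    """Model pairs whose average-rank difference reaches the critical difference."""
    cd = nemenyi_cd(rm.n_models, rm.n_folds, alpha)
    r = rm.average_ranks
    out = []
    for i in range(rm.n_models):
        for j in range(i + 1, rm.n_models):
            diff = abs(r[i] - r[j])
            if diff >= cd:
                out.append((rm.labels[i], rm.labels[j], float(diff)))
    return out


# ---------------------------------------------------------------------------
# adjusted correlation between encoded datasets


def adjusted_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Adjusted squared Pearson correlation:
    r2_adj = 1 - ((n-1)/(n-2)) * (1 - r^2(x, y)).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("adjusted_r2 needs two equal-length vectors")
    n = a.size
    if n < 3:
        raise InvalidParameterError(f"adjusted_r2 needs n >= 3, got {n}")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("adjusted_r2 undefined for a constant vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(1.0 - (n - 1) / (n - 2) * (1.0 - r**2))


def _adjusted_r2_cross(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Matrix of r2_adj between all column pairs of X and Y (vectorised)."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    xn = np.linalg.norm(Xc, axis=0)
    yn = np.linalg.norm(Yc, axis=0)
    r = (Xc.T @ Yc) / np.outer(xn, yn)
    return 1.0 - (n - 1) / (n - 2) * (1.0 - r**2)


def rv_adjusted(X: np.ndarray, Y: np.ndarray) -> float:
    """Adjusted RV-coefficient between two column-feature matrices.

    RV_adj = sum_ij r2_adj(x_i, y_j) /
             sqrt(sum_ij r2_adj(x_i, x_j) * sum_ij r2_adj(y_i, y_j)).

    Constant columns, for which the adjusted correlation is undefined,
    are excluded on both sides; a matrix with no varying column raises.
    RV_adj(X, X) = 1 exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise InvalidParameterError(
            f"row-count mismatch: {X.shape[0]} vs {Y.shape[0]}"
        )
    n = X.shape[0]
    if n < 3:
        raise InvalidParameterError(f"rv_adjusted needs n >= 3 rows, got {n}")
    X = X[:, X.std(axis=0) > 0]
    Y = Y[:, Y.std(axis=0) > 0]
    if X.shape[1] == 0 or Y.shape[1] == 0:
        raise UndefinedStatisticError("rv_adjusted undefined: no non-constant columns")
    num = float(_adjusted_r2_cross(X, Y).sum())
    dx = float(_adjusted_r2_cross(X, X).sum())
    dy = float(_adjusted_r2_cross(Y, Y).sum())
    return num / float(np.sqrt(dx * dy))


def top_k_correlation(
    mean_f1: Mapping[str, float],
    encoded: Mapping[str, np.ndarray],
    k_top: int,
) -> pd.DataFrame:
    """Pairwise adjusted-RV matrix over the k_top specs with best mean F1.

    Specs are ranked by descending mean F1 with lexicographic spec id as
    the tie-break; ``encoded`` maps spec id to its encoded matrix (rows
    already intersected to shared records).
    """
    if not mean_f1:
        raise InvalidParameterError("empty metric input")
    if k_top < 1 or k_top > len(mean_f1):
        raise InvalidParameterError(f"k_top={k_top} outside 1..{len(mean_f1)}")
    order = sorted(mean_f1, key=lambda s: (-mean_f1[s], s))[:k_top]
    out = np.ones((k_top, k_top))
    for i in range(k_top):
        for j in range(i + 1, k_top):
            out[i, j] = out[j, i] = rv_adjusted(encoded[order[i]], encoded[order[j]])
    return pd.DataFrame(out, index=order, columns=order)


# ---------------------------------------------------------------------------
# class separation


def davies_bouldin(features: np.ndarray, classes: Sequence[int]) -> float:
    """Davies-Bouldin index of the two class clusters (lower = better separated).

    Per cluster: centroid and mean euclidean point-to-centroid dispersion
    S_i; the score is the mean over clusters of max_j (S_i + S_j) / d(c_i, c_j).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(classes, dtype=int)
    groups = [X[y == c] for c in (0, 1)]
    if any(len(g) < 2 for g in groups):
        raise InvalidParameterError("davies_bouldin needs >= 2 points in each class")
    cents = [g.mean(axis=0) for g in groups]
    disps = [float(np.mean(np.linalg.norm(g - c, axis=1))) for g, c in zip(groups, cents)]
    dist = float(np.linalg.norm(cents[0] - cents[1]))
    if dist == 0:
        raise UndefinedStatisticError("coincident class centroids")
    ratio = (disps[0] + disps[1]) / dist
    return float(ratio)  # with two clusters both per-cluster maxima equal this ratio


# ---------------------------------------------------------------------------
# cross-dataset group ranking and clustering


def rank_groups(
    mean_f1_per_dataset: Mapping[str, Mapping[str, float]],
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Rank encoding groups per dataset by their best member's mean F1.

    The group representative is the member spec with the highest mean F1;
    rank 1 = best group, ties receive average ranks.  Returns a
    (dataset x group) DataFrame of ranks.
    """
    datasets = list(mean_f1_per_dataset)
    groups = sorted(set(grouping.values()))
    scores = pd.DataFrame(index=datasets, columns=groups, dtype=float)
    for ds, table in mean_f1_per_dataset.items():
        best: dict[str, float] = {}
        for spec_id, f1 in table.items():
            if spec_id not in grouping:
                raise InvalidParameterError(f"spec {spec_id!r} missing from grouping map")
            g = grouping[spec_id]
            best[g] = max(best.get(g, -np.inf), f1)
        for g in groups:
            scores.loc[ds, g] = best.get(g, 0.0)  # missing group scores count as 0
    ranks = scores.apply(lambda row: sps.rankdata(-row.values, method="average"), axis=1,
                         result_type="expand")
    ranks.columns = groups
    return ranks


@dataclass
class MergeTree:
    """UPGMA merge tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_merges(self) -> int:
        return self.linkage.shape[0]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Serialise the tree as Newick with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            lb = (node.dist - left.dist) / 2.0 if not left.is_leaf() else node.dist / 2.0
            rb = (node.dist - right.dist) / 2.0 if not right.is_leaf() else node.dist / 2.0
            return f"({walk(left)}:{lb:.6g},{walk(right)}:{rb:.6g})"

        return walk(tree) + ";"


def upgma_cluster(score_matrix: pd.DataFrame, axis: str = "datasets") -> MergeTree:
    """Average-linkage (UPGMA) clustering on euclidean distances.

    ``axis='datasets'`` clusters the rows, ``axis='groups'`` the columns.
    Missing scores must be imputed beforehand (the ranking layer imputes
    absent group scores as 0).
    """
    if axis not in ("datasets", "groups"):
        raise InvalidParameterError(f"axis must be 'datasets' or 'groups', got {axis!r}")
    mat = score_matrix if axis == "datasets" else score_matrix.T
    if mat.shape[0] < 2:
        raise InvalidParameterError("need at least two items to cluster")
    if mat.isna().any().any():
        raise InvalidParameterError("score matrix contains missing values")
    link = hierarchy.linkage(pdist(mat.values, metric="euclidean"), method="average")
    return MergeTree(link, [str(i) for i in mat.index])
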