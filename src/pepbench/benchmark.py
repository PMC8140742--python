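"""Repeated stratified cross-validation harness and performance metrics.

Each encoded dataset is evaluated with a pluggable probabilistic
classifier under a k-fold stratified CV repeated several times (defaults
k=5, 10 repeats, hence 50 fold rows).  Per fold the harness stores the
held-out record ids, true classes, predicted class-1 probabilities and
thresholded predictions; metrics (F1, MCC, precision, recall,
specificity) are computed per fold row.

The paired two-group variant reduces two encoded datasets to their shared
records and applies the identical seed-driven fold partition to both, so
fold row i of both results covers the same sequences — the prerequisite
for classifier-similarity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from pepbench.encode import EncodedDataset
from pepbench.errors import InvalidParameterError

#: Probability at or above which a record is called class 1.
PROBABILITY_THRESHOLD = 0.5


class ProbabilisticClassifier(Protocol):
    """Minimal classifier contract: fit on features/classes, emit P(class=1)."""

    def fit(self, features: np.ndarray, classes: np.ndarray) -> None: ...

    def predict_probability(self, features: np.ndarray) -> np.ndarray: ...


class RandomForestModel:
    """Default model: random forest with library defaults and a fixed seed."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._model: RandomForestClassifier | None = None

    def fit(self, features: np.ndarray, classes: np.ndarray) -> None:
        self._model = RandomForestClassifier(random_state=self.seed)
        self._model.fit(features, classes)

    def predict_probability(self, features: np.ndarray) -> np.ndarray:
        assert self._model is not None, "fit before predict"
        proba = self._model.predict_proba(features)
        class_index = {c: i for i, c in enumerate(self._model.classes_)}
        if 1 not in class_index:  # cannot happen under stratified folds
            return np.zeros(len(features))
        return proba[:, class_index[1]]


ClassifierFactory = Callable[[int], ProbabilisticClassifier]


def default_classifier_factory(seed: int) -> ProbabilisticClassifier:
    return RandomForestModel(seed)


@dataclass
class FoldRow:
    """One CV fold: held-out ids with truth, probabilities and calls."""

    repeat: int
    fold: int
    ids: list[str]
    y_true: np.ndarray
    proba: np.ndarray
    y_pred: np.ndarray


@dataclass
class CVResult:
    """All fold rows of one repeated CV run for one encoding spec."""

    spec: object  # EncodingSpec
    rows: list[FoldRow] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format record-level table (spec, repeat, fold, id, truth, proba, call)."""
        recs = []
        for row in self.rows:
            for rid, t, p, c in zip(row.ids, row.y_true, row.proba, row.y_pred):
                recs.append(
                    {
                        "spec": getattr(self.spec, "id", str(self.spec)),
                        "repeat": row.repeat,
                        "fold": row.fold,
                        "id": rid,
                        "y_true": int(t),
                        "proba": float(p),
                        "y_pred": int(c),
                    }
                )
        return pd.DataFrame(recs)


def _check_cv_inputs(y: np.ndarray, k: int, repeats: int) -> None:
    if k < 2:
        raise InvalidParameterError(f"k must be >= 2, got {k}")
    if repeats < 1:
        raise InvalidParameterError(f"repeats must be >= 1, got {repeats}")
    if len(y) < k:
        raise InvalidParameterError(f"n={len(y)} < k={k}")
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise InvalidParameterError("both classes must be present")
    if counts.min() < k:
        raise InvalidParameterError(
            f"minority class has {counts.min()} records < k={k}; stratification impossible"
        )


def _run_cv(
    X: np.ndarray,
    y: np.ndarray,
    ids: list[str],
    spec,
    k: int,
    repeats: int,
    seed: int,
    classifier_factory: ClassifierFactory,
) -> CVResult:
    result = CVResult(spec)
    for rep in range(repeats):
        # repetition r shuffles folds with seed + r, so repeats differ but the
        # whole run is reproducible
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold, (train, test) in enumerate(splitter.split(X, y)):
            model = classifier_factory(seed)
            model.fit(X[train], y[train])
            proba = np.asarray(model.predict_probability(X[test]), dtype=float)
            if proba.min() < 0 or proba.max() > 1:
                raise InvalidParameterError("classifier returned probabilities outside [0, 1]")
            y_pred = (proba >= PROBABILITY_THRESHOLD).astype(int)
            result.rows.append(
                FoldRow(
                    repeat=rep,
                    fold=fold,
                    ids=[ids[i] for i in test],
                    y_true=y[test].copy(),
                    proba=proba,
                    y_pred=y_pred,
                )
            )
    return result


def repeated_stratified_cv(
    encoded: EncodedDataset,
    labels: Mapping[str, int],
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    classifier_factory: ClassifierFactory = default_classifier_factory,
) -> CVResult:
    """Repeated stratified k-fold CV of one encoded dataset.

    Produces k * repeats fold rows (50 under the defaults).  Class calls
    threshold the class-1 probability at 0.5 (ties to class 1).
    """
    ids = list(encoded.row_ids)
    y = np.array([labels[i] for i in ids], dtype=int)
    _check_cv_inputs(y, k, repeats)
    return _run_cv(encoded.matrix, y, ids, encoded.spec, k, repeats, seed, classifier_factory)


def paired_two_group_cv(
    e1: EncodedDataset,
    e2: EncodedDataset,
    labels: Mapping[str, int],
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    classifier_factory: ClassifierFactory = default_classifier_factory,
) -> tuple[CVResult, CVResult]:
    """CV two encoded datasets on their shared records with identical folds.

    Both matrices are reduced to the intersection of their record ids
    (e.g. when a structure approximation dropped sequences from one of
    them); one seed-driven fold partition is then applied to both, so the
    i-th fold row of both results holds predictions for the same records.
    """
    shared = [rid for rid in e1.row_ids if rid in set(e2.row_ids)]
    if not shared:
        raise InvalidParameterError("empty record-id intersection")
    a = e1.subset_rows(shared)
    b = e2.subset_rows(shared)
    order = {rid: i for i, rid in enumerate(shared)}
    b_perm = sorted(range(len(b.row_ids)), key=lambda i: order[b.row_ids[i]])
    b = EncodedDataset(
        b.spec, [b.row_ids[i] for i in b_perm], b.feature_names, b.matrix[b_perm], b.dropped
    )
    y = np.array([labels[i] for i in shared], dtype=int)
    _check_cv_inputs(y, k, repeats)
    res1 = _run_cv(a.matrix, y, shared, a.spec, k, repeats, seed, classifier_factory)
    res2 = _run_cv(b.matrix, y, shared, b.spec, k, repeats, seed, classifier_factory)
    return res1, res2


# ---------------------------------------------------------------------------
# performance metrics


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) counts of binary predictions."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    return tp, fp, fn, tn


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """The five benchmark metrics with explicit zero-denominator conventions.

    Precision/recall/specificity fall back to 0 on an empty denominator;
    MCC is 0 when any marginal is empty; F1 is 1 when there are neither
    true nor predicted positives (perfect agreement on all-negatives),
    else 0 on an empty denominator.
    """
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    if tp + fn == 0 and tp + fp == 0:
        f1 = 1.0
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {
        "f1": float(f1),
        "mcc": float(mcc),
        "precision": float(precision),
        "recall": float(recall),
        "specificity": float(specificity),
    }


METRIC_NAMES = ("f1", "mcc", "precision", "recall", "specificity")


def compute_metrics(cv: CVResult) -> pd.DataFrame:
    """Per-fold-row metric table (columns: spec, repeat, fold, five metrics)."""
    recs = []
    for row in cv.rows:
        m = metrics_from_counts(*confusion_counts(row.y_true, row.y_pred))
        recs.append(
            {"spec": getattr(cv.spec, "id", str(cv.spec)), "repeat": row.repeat,
             "fold": row.fold, **m}
        )
    return pd.DataFrame(recs)


def mean_f1(cv: CVResult) -> float:
    """Mean F1 over all fold rows."""
    return float(compute_metrics(cv)["f1"].mean())
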