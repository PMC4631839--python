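"""Nearest-neighbour classification and binary evaluation metrics.

The built-in classifier is 1-NN under Euclidean distance.  SVM and
multilayer-perceptron comparators are exposed behind the same harness
via scikit-learn.

.. note::
   The positive class defaults to ``"normal"``: sensitivity counts
   correctly classified *normal* beats and specificity correctly
   classified *abnormal* beats.  This is the opposite of the usual
   clinical convention; pass ``positive_label`` to flip it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .feature_select import FeatureMask

__all__ = [
    "ConfusionCounts",
    "ClassificationReport",
    "UndefinedMetricWarning",
    "knn_distance",
    "knn_classify",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "stratified_split",
    "evaluate_split",
    "evaluate_pipeline",
    "CLASSIFIERS",
]

CLASSIFIERS = ("knn", "svm", "mlp-lm", "mlp-scg")


class UndefinedMetricWarning(UserWarning):
    """A metric's denominator was zero; NaN returned instead of a crash."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


def knn_distance(y: Sequence[float], z: Sequence[float]) -> float:
    """Euclidean distance between two equal-length vectors."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.shape != z.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sqrt(np.sum((y - z) ** 2)))


def knn_classify(
    train: np.ndarray,
    labels: Sequence,
    query: Sequence[float],
    k: int = 1,
):
    """Label of the k nearest training rows (k = 1 by default).

    Distance ties resolve to the lower training-row index.  For k > 1 a
    majority vote is taken; vote ties go to the smaller label in sort
    order.
    """
    X = np.asarray(train, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    if not (1 <= k <= X.shape[0]):
        raise ValueError("k must lie in [1, n_train]")
    q = np.asarray(query, dtype=float)
    dist = np.sqrt(np.sum((X - q) ** 2, axis=1))
    if k == 1:
        return y[int(np.argmin(dist))]
    order = np.argsort(dist, kind="stable")[:k]
    votes, counts = np.unique(y[order], return_counts=True)
    return votes[np.argmax(counts == counts.max())]


def confusion(
    predicted: Sequence,
    truth: Sequence,
    positive_label="normal",
) -> ConfusionCounts:
    """TP/TN/FP/FN counts with a configurable positive class."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted/truth length mismatch")
    classes = np.unique(np.concatenate([pred, true]))
    if len(classes) > 2:
        raise ValueError("confusion counts require binary labels")
    pos_t = true == positive_label
    pos_p = pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _pct(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", UndefinedMetricWarning,
                      stacklevel=3)
        return math.nan
    return 100.0 * num / den


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN) as a percentage."""
    return _pct(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP) as a percentage."""
    return _pct(c.tn, c.tn + c.fp, "specificity")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total as a percentage."""
    return _pct(c.tp + c.tn, c.total, "accuracy")


@dataclass(frozen=True)
class ClassificationReport:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    classifier: str
    mask_indices: tuple[int, ...] | None
    train_size: int
    test_size: int
    seed: int

    def recompute(self) -> tuple[float, float, float]:
        """Metrics re-derived from the stored counts (round-trip check)."""
        return sensitivity(self.counts), specificity(self.counts), accuracy(self.counts)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "classifier": self.classifier,
            "mask_indices": list(self.mask_indices) if self.mask_indices else None,
            "train_size": self.train_size,
            "test_size": self.test_size,
            "seed": self.seed,
        }


def stratified_split(
    labels: Sequence, train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled row indices for a train/test split."""
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_rows, test_rows = [], []
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        rows = rows[rng.permutation(len(rows))]
        cut = int(round(train_frac * len(rows)))
        cut = min(max(cut, 1), len(rows) - 1)
        train_rows.append(rows[:cut])
        test_rows.append(rows[cut:])
    return np.sort(np.concatenate(train_rows)), np.sort(np.concatenate(test_rows))


def _knn_predict(train: np.ndarray, labels: np.ndarray, queries: np.ndarray):
    dist = cdist(queries, train)
    return labels[np.argmin(dist, axis=1)]


def _build_sklearn(classifier: str, seed: int):
    if classifier == "svm":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", random_state=seed)
    if classifier in ("mlp-lm", "mlp-scg"):
        from sklearn.neural_network import MLPClassifier

        # 10-unit hidden layer; stop criteria mirror the 1000-iteration /
        # 1e-3 error budget of the reference setup.  lbfgs stands in for
        # the Levenberg-Marquardt solver, sgd for scaled conjugate
        # gradient (neither is available in scikit-learn).
        solver = "lbfgs" if classifier == "mlp-lm" else "sgd"
        return MLPClassifier(
            hidden_layer_sizes=(10,),
            solver=solver,
            max_iter=1000,
            tol=1e-3,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier {classifier!r}")


def evaluate_split(
    train_X: np.ndarray,
    train_y: Sequence,
    test_X: np.ndarray,
    test_y: Sequence,
    mask: FeatureMask | None = None,
    classifier: str = "knn",
    positive_label="normal",
    seed: int = 0,
) -> ClassificationReport:
    """Fit the named classifier on masked columns and score the test set."""
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    test_y = np.asarray(test_y)
    if mask is not None:
        cols = mask.as_array()
        train_X = train_X[:, cols]
        test_X = test_X[:, cols]
    if classifier == "knn":
        pred = _knn_predict(train_X, train_y, test_X)
    else:
        model = _build_sklearn(classifier, seed)
        model.fit(train_X, train_y)
        pred = model.predict(test_X)
    counts = confusion(pred, test_y, positive_label=positive_label)
    return ClassificationReport(
        counts=counts,
        sensitivity=sensitivity(counts),
        specificity=specificity(counts),
        accuracy=accuracy(counts),
        classifier=classifier,
        mask_indices=None if mask is None else mask.indices,
        train_size=len(train_y),
        test_size=len(test_y),
        seed=seed,
    )


def evaluate_pipeline(
    beats,
    labels: Sequence,
    mask: FeatureMask | None = None,
    classifier: str = "knn",
    train_frac: float = 0.64,
    positive_label="normal",
    seed: int = 0,
) -> ClassificationReport:
    """Stratified split, masked fit, held-out evaluation."""
    X = np.asarray(getattr(beats, "beats", beats), dtype=float)
    y = np.asarray(labels)
    if len(y) != X.shape[0]:
        raise ValueError("labels length must match beat count")
    train_rows, test_rows = stratified_split(y, train_frac, seed)
    return evaluate_split(
        X[train_rows], y[train_rows], X[test_rows], y[test_rows],
        mask=mask, classifier=classifier,
        positive_label=positive_label, seed=seed,
    )
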