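"""Mapping optimizer positions to feature subsets and fitness functions.

A candidate position is a continuous D-vector; the k coordinates with
the largest magnitude name the selected features.  Two fitness modes are
available: ``wrapper`` (cross-validated 1-NN misclassification on the
masked columns — the default) and ``rosenbrock`` (a label-blind
benchmark evaluated on the raw position, retained for comparison).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .bat_core import (
    ConfigError,
    OptimizerTrace,
    SwarmConfig,
    rosenbrock,
    run_optimizer,
)

__all__ = [
    "FeatureMask",
    "SelectionResult",
    "DegenerateLabelsError",
    "position_to_mask",
    "make_folds",
    "wrapper_fitness",
    "rosenbrock_fitness",
    "select_features",
    "exhaustive_best_subset",
]


class DegenerateLabelsError(ValueError):
    """Fewer than two classes present where a classifier needs both."""


@dataclass(frozen=True)
class FeatureMask:
    """An ordered set of k selected column indices out of n_features."""

    indices: tuple[int, ...]
    n_features: int

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(idx) == 0:
            raise ValueError("mask must select at least one feature")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("mask indices must be strictly increasing")
        if idx[0] < 0 or idx[-1] >= self.n_features:
            raise ValueError("mask indices out of range")
        object.__setattr__(self, "indices", idx)

    @property
    def k(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


@dataclass(frozen=True)
class SelectionResult:
    mask: FeatureMask
    fitness: float
    trace: OptimizerTrace
    mode: str  # fitness mode: "wrapper" | "rosenbrock"
    optimizer: str  # "ba" | "iba"


def position_to_mask(x: Sequence[float], k: int, n_features: int | None = None) -> FeatureMask:
    """Indices of the k largest |x_j|; ties resolved toward lower index."""
    arr = np.asarray(x, dtype=float)
    d = arr.shape[0] if n_features is None else int(n_features)
    if arr.shape[0] != d:
        raise ValueError("position length does not match n_features")
    if not (1 <= k <= d):
        raise ValueError(f"k must lie in [1, {d}], got {k}")
    order = np.argsort(-np.abs(arr), kind="stable")
    return FeatureMask(indices=tuple(sorted(int(i) for i in order[:k])), n_features=d)


def make_folds(labels: Sequence, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment, fixed by beat identity and seed.

    Returns an integer array of fold ids in [0, n_folds).  Within each
    class, row positions are shuffled once and dealt round-robin, so the
    assignment is a pure function of (labels, n_folds, seed).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        rows = np.flatnonzero(labels == cls)
        perm = rng.permutation(len(rows))
        folds[rows[perm]] = np.arange(len(rows)) % n_folds
    return folds


def _beats_array(beats) -> np.ndarray:
    arr = getattr(beats, "beats", beats)
    return np.asarray(arr, dtype=float)


def wrapper_fitness(
    mask: FeatureMask,
    beats,
    labels: Sequence,
    folds: np.ndarray,
) -> float:
    """Cross-validated 1-NN misclassification rate on the masked columns.

    Errors are pooled over folds, giving a rate in [0, 1]; lower is
    better.  Deterministic given the fold assignment.  Nearest-neighbour
    ties resolve to the lower training-row index (argmin order).
    """
    X = _beats_array(beats)
    y = np.asarray(labels)
    if mask.n_features != X.shape[1]:
        raise ValueError("mask width does not match beat matrix width")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("wrapper fitness needs at least two classes")
    Xm = X[:, mask.as_array()]
    folds = np.asarray(folds)
    wrong = 0
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test
        dist = cdist(Xm[test], Xm[train])
        nearest = np.argmin(dist, axis=1)
        wrong += int(np.sum(y[train][nearest] != y[test]))
    return wrong / len(y)


def rosenbrock_fitness(x: Sequence[float]) -> float:
    """Label-blind benchmark fitness on the raw position vector."""
    return float(rosenbrock(x))


def _default_bounds(config: SwarmConfig, d: int) -> SwarmConfig:
    if config.bounds is None:
        return replace(config, bounds=tuple((-1.0, 1.0) for _ in range(d)))
    if config.dim != d:
        raise ConfigError("config bounds dimension does not match beat width")
    return config


def select_features(
    beats,
    labels: Sequence,
    k: int,
    config: SwarmConfig,
    optimizer: str = "iba",
    fitness: str = "wrapper",
    n_folds: int = 5,
    folds: np.ndarray | None = None,
) -> SelectionResult:
    """Run BA/IBA over D-dimensional positions and return the best k-mask.

    Wrapper mode fixes stratified folds (from ``config.seed`` unless an
    explicit assignment is given) before the search, so the objective is
    a pure function of the mask; evaluations are cached per mask.
    """
    X = _beats_array(beats)
    d = X.shape[1]
    if not (1 <= k <= d):
        raise ValueError(f"k must lie in [1, {d}]")
    config = _default_bounds(config, d)

    if fitness == "wrapper":
        y = np.asarray(labels)
        if folds is None:
            folds = make_folds(y, n_folds=n_folds, seed=config.seed)
        cache: dict[tuple[int, ...], float] = {}

        def objective(x: np.ndarray) -> float:
            mask = position_to_mask(x, k, d)
            val = cache.get(mask.indices)
            if val is None:
                val = wrapper_fitness(mask, X, y, folds)
                cache[mask.indices] = val
            return val

    elif fitness == "rosenbrock":
        objective = rosenbrock_fitness
    else:
        raise ValueError(f"unknown fitness mode {fitness!r}")

    if optimizer not in ("ba", "iba"):
        raise ValueError(f"unknown optimizer {optimizer!r}")
    best_x, best_f, trace = run_optimizer(config, objective, mode=optimizer)
    return SelectionResult(
        mask=position_to_mask(best_x, k, d),
        fitness=best_f,
        trace=trace,
        mode=fitness,
        optimizer=optimizer,
    )


def exhaustive_best_subset(
    beats,
    labels: Sequence,
    k: int,
    folds: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
    cap: int = 100_000,
) -> tuple[FeatureMask, float]:
    """Enumerate all k-subsets and return the wrapper-fitness optimum.

    Serves as a brute-force oracle; ties go to the lexicographically
    smallest index list (enumeration order).  Refuses instances with
    more than ``cap`` subsets.
    """
    X = _beats_array(beats)
    y = np.asarray(labels)
    d = X.shape[1]
    n_subsets = math.comb(d, k)
    if n_subsets > cap:
        raise ValueError(f"C({d},{k}) = {n_subsets} exceeds cap {cap}")
    if folds is None:
        folds = make_folds(y, n_folds=n_folds, seed=seed)
    best_mask: FeatureMask | None = None
    best_fit = math.inf
    for combo in itertools.combinations(range(d), k):
        mask = FeatureMask(indices=combo, n_features=d)
        fit = wrapper_fitness(mask, X, y, folds)
        if fit < best_fit:
            best_fit = fit
            best_mask = mask
    assert best_mask is not None
    return best_mask, best_fit
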