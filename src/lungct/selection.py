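"""Hybrid spiral-optimization / rough-set feature selection.

A multipoint spiral search rotates and contracts candidate points about the
incumbent best through the fixed n-dimensional rotation matrix

    R = [[0_{n-1}^T, -1],
         [I_{n-1},   0_{n-1}]]

with step rate r(k) either constant (periodic-descent schedule,
r = delta^(1/k_max)) or the convergence schedule (r = 1 for
k* <= k <= k*+2n-1, else delta^(1/(2n)) with delta = 0.5).  Points live in
[0, 1]^n and binarize at 0.5 into feature subsets; fitness rewards
rough-set dependency of the decision attribute on the subset
(gamma = |positive region| / |U|) and, secondarily, small subsets:

    fitness(B) = 0.9 * gamma(B) + 0.1 * (1 - |B|/n).

After the search, a backward-elimination pass drops attributes whose removal
preserves the full-table dependency degree, so the returned subset is
minimal-by-inclusion and always satisfies gamma(B) = gamma(full).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SpiralConfig", "DecisionTable", "rotation_matrix", "step_rate",
    "spiral_step", "gamma_dependency", "select_features",
    "exhaustive_reduct", "SpiralRoughSetSelector", "discretize_table",
]

ALPHA, BETA = 0.9, 0.1  # fitness weights: dependency vs subset size


@dataclass
class SpiralConfig:
    n_points: int = 30
    k_max: int = 100
    delta: float = 0.5
    mode: str = "convergence"  # or "periodic_descent"
    k_star: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("need at least two spiral points")
        if not (0.0 < self.delta <= 1.0):
            raise ValueError("delta must lie in (0, 1]")
        if self.mode not in ("convergence", "periodic_descent"):
            raise ValueError("unknown step-rate mode")


@dataclass
class DecisionTable:
    """Discretized condition attributes plus a binary decision attribute."""

    X: np.ndarray  # objects x attributes, integer bins
    d: np.ndarray  # binary decisions

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.d = np.asarray(self.d).astype(int)
        if self.X.ndim != 2 or self.X.shape[0] != self.d.size:
            raise ValueError("table shapes are inconsistent")
        if np.any(pd.isna(self.X)):
            raise ValueError("missing values are not allowed")

    @property
    def n_attributes(self):
        return self.X.shape[1]


def rotation_matrix(n: int) -> np.ndarray:
    """The n x n block rotation [[0^T, -1], [I, 0]] (orthogonal; R^(2n)=I)."""
    if n < 2:
        raise ValueError("rotation matrix needs n >= 2")
    R = np.zeros((n, n))
    R[0, -1] = -1.0
    R[1:, :-1] = np.eye(n - 1)
    return R


def step_rate(k: int, cfg: SpiralConfig, n: int) -> float:
    """Contraction rate r(k) for iteration k in dimension n."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if cfg.mode == "periodic_descent":
        return cfg.delta ** (1.0 / cfg.k_max)
    if cfg.k_star <= k <= cfg.k_star + 2 * n - 1:
        return 1.0
    return cfg.delta ** (1.0 / (2 * n))


def spiral_step(points: np.ndarray, center: np.ndarray, r: float,
                R: np.ndarray) -> np.ndarray:
    """x <- c + r * R (x - c) for each row of ``points``."""
    diff = points - center
    return center + r * (diff @ R.T)


def _group_ids(X: np.ndarray, cols) -> np.ndarray:
    cols = np.asarray(cols)
    if cols.size == 0:
        return np.zeros(X.shape[0], dtype=np.int64)
    _, inv = np.unique(X[:, cols], axis=0, return_inverse=True)
    return inv


def gamma_dependency(table: DecisionTable, subset) -> float:
    """Dependency degree gamma(B) = |POS_B(d)| / |U|.

    The positive region unites the B-indiscernibility classes whose objects
    all share one decision value.
    """
    subset = np.asarray(subset)
    if subset.dtype == bool:
        subset = np.flatnonzero(subset)
    inv = _group_ids(table.X, subset)
    n_groups = inv.max() + 1
    # a group is pure iff min and max decision within it coincide
    dmin = np.full(n_groups, 2)
    dmax = np.full(n_groups, -1)
    np.minimum.at(dmin, inv, table.d)
    np.maximum.at(dmax, inv, table.d)
    pure = dmin == dmax
    sizes = np.bincount(inv, minlength=n_groups)
    return float(sizes[pure].sum() / table.d.size)


def _fitness(table: DecisionTable, mask: np.ndarray) -> float:
    n = table.n_attributes
    return ALPHA * gamma_dependency(table, mask) + BETA * (1.0 - mask.sum() / n)


def _repair(point: np.ndarray) -> np.ndarray:
    mask = point >= 0.5
    if not mask.any():  # activate the coordinate nearest the 0.5 cut
        mask = mask.copy()
        mask[np.argmin(np.abs(point - 0.5))] = True
    return mask


def _rank_condition_ok(points: np.ndarray, R: np.ndarray, n: int) -> bool:
    """Initialization condition: spans of rotated pairwise differences must
    be full rank (checked as min over i of max over j)."""
    m = len(points)
    powers = [np.linalg.matrix_power(R, p) for p in range(2 * n)]
    best_overall = n + 1
    for i in range(m):
        best_j = 0
        for j in range(m):
            if i == j:
                continue
            d = points[j] - points[i]
            span = np.column_stack([P @ d for P in powers])
            best_j = max(best_j, np.linalg.matrix_rank(span))
            if best_j == n:
                break
        best_overall = min(best_overall, best_j)
        if best_overall < n:
            return False
    return True


def _backward_eliminate(table: DecisionTable, mask: np.ndarray,
                        gamma_full: float) -> np.ndarray:
    """Drop attributes (highest index first) while gamma stays at the
    full-table level; repeats until minimal by inclusion."""
    mask = mask.copy()
    changed = True
    while changed and mask.sum() > 1:
        changed = False
        for a in sorted(np.flatnonzero(mask), reverse=True):
            trial = mask.copy()
            trial[a] = False
            if gamma_dependency(table, trial) >= gamma_full - 1e-12:
                mask = trial
                changed = True
    return mask


def select_features(table: DecisionTable, cfg: SpiralConfig | None = None
                    ) -> np.ndarray:
    """Spiral search over subset indicators, refined by backward
    elimination; returns a boolean mask.  Deterministic per ``cfg.seed``."""
    cfg = cfg or SpiralConfig()
    n = table.n_attributes
    if n < 2:
        raise ValueError("need at least two attributes")
    if all(len(np.unique(table.X[:, j])) == 1 for j in range(n)):
        raise ValueError("all attributes are constant")
    rng = np.random.default_rng(cfg.seed)
    R = rotation_matrix(n)
    gamma_full = gamma_dependency(table, np.arange(n))

    for _ in range(50):  # rejection-sample a full-rank initial configuration
        points = rng.random((cfg.n_points, n))
        if _rank_condition_ok(points, R, n):
            break

    best_mask = np.ones(n, dtype=bool)
    best_fit = _fitness(table, best_mask)
    best_point = points[0].copy()
    k_last_improve = 0
    for k in range(cfg.k_max):
        for p in points:
            mask = _repair(np.clip(p, 0.0, 1.0))
            fit = _fitness(table, mask)
            if fit > best_fit + 1e-12:
                best_fit, best_mask, best_point = fit, mask, p.copy()
                k_last_improve = k
        local = SpiralConfig(cfg.n_points, cfg.k_max, cfg.delta, cfg.mode,
                             k_star=k_last_improve, seed=cfg.seed)
        r = step_rate(k, local, n)
        points = spiral_step(points, best_point, r, R)

    # feasibility: never return a subset losing dependency vs the full set
    if gamma_dependency(table, best_mask) < gamma_full - 1e-12:
        best_mask = np.ones(n, dtype=bool)
    spiral_cand = _backward_eliminate(table, best_mask, gamma_full)
    # deterministic fallback candidate: reduce the full attribute set
    full_cand = _backward_eliminate(table, np.ones(n, dtype=bool), gamma_full)
    if _fitness(table, full_cand) > _fitness(table, spiral_cand) + 1e-12:
        return full_cand
    return spiral_cand


def exhaustive_reduct(table: DecisionTable) -> np.ndarray:
    """Smallest subset preserving the full-table gamma, by exhaustive search
    over all 2^n subsets (n <= 14); ties broken lexicographically."""
    from itertools import combinations

    n = table.n_attributes
    if n > 14:
        raise ValueError("exhaustive search is limited to n <= 14")
    gamma_full = gamma_dependency(table, np.arange(n))
    for size in range(1, n + 1):
        for combo in combinations(range(n), size):
            if gamma_dependency(table, np.array(combo)) >= gamma_full - 1e-12:
                mask = np.zeros(n, dtype=bool)
                mask[list(combo)] = True
                return mask
    return np.ones(n, dtype=bool)


def discretize_table(X, y, bins: int = 4, edges=None):
    """Equal-frequency discretization into integer bins; returns the
    decision table and the bin edges (reusable on held-out data)."""
    X = np.asarray(X, dtype=np.float64)
    if edges is None:
        qs = np.linspace(0, 1, bins + 1)[1:-1]
        edges = [np.unique(np.quantile(X[:, j], qs)) for j in range(X.shape[1])]
    Xd = np.column_stack([np.searchsorted(edges[j], X[:, j], side="right")
                          for j in range(X.shape[1])])
    return DecisionTable(X=Xd, d=np.asarray(y)), edges


class SpiralRoughSetSelector(BaseEstimator):
    """sklearn-style transformer wrapping :func:`select_features`.

    Continuous features are discretized into equal-frequency bins (fit on
    the training data) before the rough-set dependency is evaluated.
    """

    def __init__(self, n_points=30, k_max=100, delta=0.5, mode="convergence",
                 bins=4, random_state=0):
        self.n_points = n_points
        self.k_max = k_max
        self.delta = delta
        self.mode = mode
        self.bins = bins
        self.random_state = random_state

    def fit(self, X, y):
        table, self.edges_ = discretize_table(X, y, bins=self.bins)
        cfg = SpiralConfig(n_points=self.n_points, k_max=self.k_max,
                           delta=self.delta, mode=self.mode,
                           seed=self.random_state)
        self.support_ = select_features(table, cfg)
        self.n_features_in_ = table.n_attributes
        return self

    def get_support(self):
        return self.support_

    def transform(self, X):
        return np.asarray(X)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
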