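"""Harris hawks optimization with elite mutation, and hyperparameter tuning
of the GOSS boosting classifier over its discrete grids.

The canonical HHO phase logic drives the population: prey escape energy
E = 2*E0*(1 - t/T) selects exploration (|E| >= 1) or exploitation (soft and
hard besiege, with Levy-flight rapid dives).  On top of that, an elite
mutation step perturbs the best 10% of hawks each generation with a Gaussian
whose scale decays as t^(-1/2); mutants are accepted only on improvement, so
the incumbent best ("rabbit") never worsens.

The tuner searches continuous [0, 1]^4 hawk positions that are projected to
the nearest points of the discrete grids for minimum-data-in-leaf, boosting
iterations, leaf count and maximum depth; the objective is mean
cross-validated classification error.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .boosting import GBDTParams, GOSSBoostingClassifier, PARAM_GRIDS

__all__ = ["hho_optimize", "tune", "HarrisHawksTuner"]


def _levy(rng, dim, beta=1.5):
    num = math.gamma(1 + beta) * np.sin(np.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma = (num / den) ** (1 / beta)
    u = rng.normal(0, sigma, dim)
    v = rng.normal(0, 1, dim)
    return u / np.abs(v) ** (1 / beta)


def hho_optimize(objective, bounds, n_hawks: int = 30, T: int = 200,
                 seed: int = 0, elite_frac: float = 0.1):
    """Minimize ``objective`` over box ``bounds`` (list of (lo, hi) pairs).

    Returns ``(best_position, best_fitness, history)`` where ``history`` is
    the monotone non-increasing incumbent fitness per iteration.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))
            and np.all(ub > lb)):
        raise ValueError("bounds must be finite with hi > lo")
    dim = lb.size
    rng = np.random.default_rng(seed)
    X = lb + rng.random((n_hawks, dim)) * (ub - lb)
    fit = np.array([objective(x) for x in X])
    best_i = int(np.argmin(fit))
    rabbit, rabbit_fit = X[best_i].copy(), float(fit[best_i])
    history = []

    n_elite = max(1, int(np.ceil(elite_frac * n_hawks)))
    for t in range(T):
        mean_pos = X.mean(axis=0)
        for i in range(n_hawks):
            E0 = rng.uniform(-1, 1)
            E = 2.0 * E0 * (1.0 - (t + 1) / T)
            J = 2.0 * (1.0 - rng.random())
            if abs(E) >= 1.0:  # exploration
                if rng.random() >= 0.5:
                    k = rng.integers(n_hawks)
                    Xn = X[k] - rng.random() * np.abs(
                        X[k] - 2 * rng.random() * X[i])
                else:
                    Xn = (rabbit - mean_pos) - rng.random() * (
                        lb + rng.random() * (ub - lb))
            else:  # exploitation: besiege variants
                r = rng.random()
                if r >= 0.5 and abs(E) >= 0.5:      # soft besiege
                    Xn = (rabbit - X[i]) - E * np.abs(J * rabbit - X[i])
                elif r >= 0.5:                       # hard besiege
                    Xn = rabbit - E * np.abs(rabbit - X[i])
                elif abs(E) >= 0.5:                  # soft besiege + dives
                    Y = rabbit - E * np.abs(J * rabbit - X[i])
                    Y = np.clip(Y, lb, ub)
                    if objective(Y) < fit[i]:
                        Xn = Y
                    else:
                        Z = np.clip(Y + rng.random(dim) * _levy(rng, dim),
                                    lb, ub)
                        Xn = Z if objective(Z) < fit[i] else X[i]
                else:                                # hard besiege + dives
                    Y = rabbit - E * np.abs(J * rabbit - mean_pos)
                    Y = np.clip(Y, lb, ub)
                    if objective(Y) < fit[i]:
                        Xn = Y
                    else:
                        Z = np.clip(Y + rng.random(dim) * _levy(rng, dim),
                                    lb, ub)
                        Xn = Z if objective(Z) < fit[i] else X[i]
            Xn = np.clip(Xn, lb, ub)
            fn = objective(Xn)
            if fn < fit[i] or abs(E) >= 1.0:
                X[i], fit[i] = Xn, fn
            if fit[i] < rabbit_fit:
                rabbit, rabbit_fit = X[i].copy(), float(fit[i])

        # elite mutation: perturb the current best hawks, greedy acceptance
        scale = 0.1 * (ub - lb) / np.sqrt(t + 1.0)
        for i in np.argsort(fit)[:n_elite]:
            trial = np.clip(X[i] + rng.normal(0, 1, dim) * scale, lb, ub)
            ft = objective(trial)
            if ft < fit[i]:
                X[i], fit[i] = trial, ft
                if ft < rabbit_fit:
                    rabbit, rabbit_fit = trial.copy(), float(ft)
        history.append(rabbit_fit)
    return rabbit, rabbit_fit, np.asarray(history)


def _project(position, grids):
    """Map a [0,1]^d hawk position to the nearest grid points."""
    names = list(grids)
    out = {}
    for u, name in zip(position, names):
        g = np.asarray(grids[name])
        idx = int(round(float(u) * (len(g) - 1)))
        out[name] = int(g[np.clip(idx, 0, len(g) - 1)])
    return out


def tune(X, y, grids=None, cv_folds: int = 3, seed: int = 0,
         n_hawks: int = 6, T: int = 10, **fixed) -> GBDTParams:
    """HHO search over the discrete hyperparameter grids.

    The objective is 1 - mean stratified-CV accuracy of the GOSS classifier;
    the returned parameters always lie exactly on the grids.
    """
    grids = {k: np.asarray(v) for k, v in (grids or PARAM_GRIDS).items()}
    if any(len(g) == 0 for g in grids.values()):
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    if cv_folds > counts[counts > 0].min():
        raise ValueError("cv_folds exceeds the size of the smallest class")
    # restrict the MDL grid to values trainable on a CV fold, if any are
    if "min_data_in_leaf" in grids:
        fold_rows = X.shape[0] * (cv_folds - 1) // cv_folds
        feasible = grids["min_data_in_leaf"][
            2 * grids["min_data_in_leaf"] <= fold_rows]
        if feasible.size:
            grids["min_data_in_leaf"] = feasible
    cache = {}

    def objective(pos):
        cfg = _project(pos, grids)
        key = tuple(sorted(cfg.items()))
        if key in cache:
            return cache[key]
        # MDL is clamped to half the fold rows exactly as the pipeline's
        # final fit clamps it, so the CV error reflects the model actually
        # trained on tiny benchmarks
        fold_rows = X.shape[0] * (cv_folds - 1) // cv_folds
        cfg = dict(cfg)
        cfg["min_data_in_leaf"] = min(cfg.get("min_data_in_leaf", 20),
                                      max(1, fold_rows // 2))
        clf = GOSSBoostingClassifier(random_state=seed, **{**cfg, **fixed})
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                              random_state=seed)
        errs = []
        for tr, te in skf.split(X, y):
            clf.fit(X[tr], y[tr])
            errs.append(1.0 - clf.score(X[te], y[te]))
        cache[key] = float(np.mean(errs))
        return cache[key]

    single = all(len(g) == 1 for g in grids.values())
    pos, _, _ = hho_optimize(objective, [(0.0, 1.0)] * len(grids),
                             n_hawks=max(2, n_hawks),
                             T=1 if single else T, seed=seed)
    cfg = _project(pos, grids)
    return GBDTParams(seed=seed, **{**cfg, **fixed})


class HarrisHawksTuner(BaseEstimator):
    """sklearn-style wrapper: ``fit`` tunes then trains a final classifier."""

    def __init__(self, grids=None, cv_folds=3, n_hawks=6, T=10,
                 random_state=0):
        self.grids = grids
        self.cv_folds = cv_folds
        self.n_hawks = n_hawks
        self.T = T
        self.random_state = random_state

    def fit(self, X, y):
        p = tune(X, y, grids=self.grids, cv_folds=self.cv_folds,
                 seed=self.random_state, n_hawks=self.n_hawks, T=self.T)
        self.best_params_ = p
        self.best_estimator_ = GOSSBoostingClassifier(
            min_data_in_leaf=p.min_data_in_leaf, n_iterations=p.n_iterations,
            num_leaves=p.num_leaves, max_depth=p.max_depth,
            learning_rate=p.learning_rate, goss_b=p.goss_b, goss_c=p.goss_c,
            random_state=self.random_state).fit(X, y)
        return self

    def predict(self, X):
        return self.best_estimator_.predict(X)

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(X)
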