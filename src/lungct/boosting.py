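"""Gradient-boosted decision trees with gradient-based one-side sampling.

Boosting minimizes the logistic loss by adding leaf-wise-grown regression
trees, F_n(x) = F_{n-1}(x) + lr * t_n(x).  At each round GOSS keeps the
top ``b``-fraction of instances by |gradient| (weight 1) and a random
``c``-fraction of the remainder, amplified by (1-b)/c so sampled gradient
sums stay unbiased.  Split points maximize the sampled variance gain

    W_k(e) = (1/o) [ (S_left)^2 / o_left + (S_right)^2 / o_right ]

where S_side sums the (amplified) gradients of sampled instances on that
side of threshold e on feature k and o_side counts them.  Trees respect a
minimum-data-in-leaf (MDL), a leaf-count cap (NL) and a depth cap (MD);
candidate thresholds come from 32 equal-width histogram bins per feature.

Exclusive feature bundling is deliberately a no-op here: the 50 dense
features extracted upstream have no mutually exclusive sparsity to bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "GBDTParams", "GBDTModel", "PARAM_GRIDS", "normalize01", "goss_sample",
    "variance_gain", "fit_gbdt", "predict_proba", "GOSSBoostingClassifier",
]

N_BINS = 32

# hyperparameter search grids for the tuner
PARAM_GRIDS = {
    "min_data_in_leaf": np.arange(20, 241, 20),
    "n_iterations": np.arange(10, 451, 10),
    "num_leaves": np.arange(20, 257),
    "max_depth": np.arange(1, 13),
}


@dataclass
class GBDTParams:
    min_data_in_leaf: int = 20      # MDL
    n_iterations: int = 100         # NTI (boosting rounds)
    num_leaves: int = 31            # NL
    max_depth: int = 6              # MD
    learning_rate: float = 0.1
    goss_b: float = 0.2
    goss_c: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.goss_b <= 1.0 and 0.0 < self.goss_c <= 1.0):
            raise ValueError("GOSS fractions must lie in (0, 1]")
        if self.goss_b + self.goss_c > 1.0 + 1e-12 and self.goss_b < 1.0:
            raise ValueError("goss_b + goss_c must not exceed 1")


@dataclass
class GBDTModel:
    trees: list
    base_score: float
    params: GBDTParams


def normalize01(y) -> np.ndarray:
    """Min-max normalization onto [0, 1]."""
    y = np.asarray(y, dtype=np.float64)
    lo, hi = y.min(), y.max()
    if hi <= lo:
        raise ValueError("cannot normalize a constant vector")
    return (y - lo) / (hi - lo)


def goss_sample(gradients, b: float, c: float, seed: int = 0):
    """GOSS instance selection.

    Returns ``(indices, weights)``: the ceil(b*o) largest-|gradient|
    instances with weight 1 and ceil(c*o) uniform draws from the remainder
    with weight (1-b)/c.  With b=1 all instances are kept at weight 1.
    """
    g = np.asarray(gradients, dtype=np.float64)
    o = g.size
    if not (0.0 < b <= 1.0 and 0.0 < c <= 1.0):
        raise ValueError("b and c must lie in (0, 1]")
    n_top = min(o, int(np.ceil(b * o)))
    order = np.argsort(-np.abs(g), kind="stable")
    top = order[:n_top]
    rest = order[n_top:]
    if b >= 1.0 or rest.size == 0:
        return np.sort(top), np.ones(n_top)
    n_rand = min(rest.size, int(np.ceil(c * o)))
    rng = np.random.default_rng(seed)
    rand = rng.choice(rest, size=n_rand, replace=False)
    idx = np.concatenate([top, rand])
    w = np.concatenate([np.ones(n_top), np.full(n_rand, (1.0 - b) / c)])
    srt = np.argsort(idx, kind="stable")
    return idx[srt], w[srt]


def variance_gain(x, gradients, weights, threshold, o: int | None = None
                  ) -> float:
    """Sampled variance gain of splitting at ``threshold`` (left: x <= e).

    ``x``/``gradients``/``weights`` describe the sampled instances (weights
    already carry the (1-b)/c amplification); ``o`` is the total instance
    count the gain is normalized by (defaults to the sampled count).
    """
    x = np.asarray(x, dtype=np.float64)
    wg = np.asarray(gradients, dtype=np.float64) * np.asarray(weights,
                                                              dtype=np.float64)
    left = x <= threshold
    n_l, n_r = int(left.sum()), int((~left).sum())
    if n_l == 0 or n_r == 0:
        raise ValueError("threshold leaves one side empty")
    o = x.size if o is None else int(o)
    return float((wg[left].sum() ** 2 / n_l + wg[~left].sum() ** 2 / n_r) / o)


# ----------------------------------------------------------------- trees


def _bin_features(X: np.ndarray):
    """32 equal-frequency histogram bins per feature; returns bin indices
    and the candidate threshold boundaries."""
    n, f = X.shape
    bins = np.zeros((n, f), dtype=np.int16)
    bounds = []
    for j in range(f):
        if X[:, j].max() <= X[:, j].min():
            bounds.append(np.array([]))
            continue
        qs = np.quantile(X[:, j], np.linspace(0, 1, N_BINS + 1)[1:-1])
        bnd = np.unique(qs)
        bounds.append(bnd)
        bins[:, j] = np.digitize(X[:, j], bnd, right=True)
    return bins, bounds


class _Leaf:
    __slots__ = ("rows", "sub", "w", "g", "h", "depth", "best")

    def __init__(self, rows, sub, w, g, h, depth):
        self.rows = rows      # full-data row indices at this node
        self.sub = sub        # sampled row indices
        self.w = w            # sampled weights
        self.g = g            # sampled gradients
        self.h = h            # sampled hessians
        self.depth = depth
        self.best = None      # (gain, feature, bin)


def _find_best_split(leaf: _Leaf, bins, bounds, mdl: int):
    best = None
    if leaf.sub.size == 0:
        return None
    wg = leaf.w * leaf.g
    sub_bins = bins[leaf.sub]
    full_bins = bins[leaf.rows]
    o = leaf.sub.size
    parent = wg.sum() ** 2 / o
    for j in range(bins.shape[1]):
        if bounds[j].size == 0:
            continue
        hist_wg = np.bincount(sub_bins[:, j], weights=wg, minlength=N_BINS)
        hist_ns = np.bincount(sub_bins[:, j], minlength=N_BINS)
        hist_nf = np.bincount(full_bins[:, j], minlength=N_BINS)
        cum_wg = np.cumsum(hist_wg)[:-1]
        cum_ns = np.cumsum(hist_ns)[:-1]
        cum_nf = np.cumsum(hist_nf)[:-1]
        tot_wg, tot_ns, tot_nf = hist_wg.sum(), o, leaf.rows.size
        ok = ((cum_nf >= mdl) & (tot_nf - cum_nf >= mdl)
              & (cum_ns > 0) & (tot_ns - cum_ns > 0))
        if not ok.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            w_gain = (cum_wg ** 2 / cum_ns
                      + (tot_wg - cum_wg) ** 2 / (tot_ns - cum_ns)) / o
        w_gain = np.where(ok, w_gain, -np.inf)
        t = int(np.argmax(w_gain))
        gain = w_gain[t] - parent / o
        if best is None or gain > best[0]:
            best = (float(gain), j, t)
    return best


def _leaf_value(leaf: _Leaf) -> float:
    if leaf.sub.size == 0:
        return 0.0
    num = -(leaf.w * leaf.g).sum()
    den = (leaf.w * leaf.h).sum() + 1e-6
    return float(num / den)


def _grow_tree(X, bins, bounds, g, h, sub_idx, sub_w, p: GBDTParams):
    """Leaf-wise growth: repeatedly split the leaf with the largest gain."""
    n = X.shape[0]
    root = _Leaf(np.arange(n), sub_idx, sub_w, g[sub_idx], h[sub_idx], 0)
    root.best = _find_best_split(root, bins, bounds, p.min_data_in_leaf)
    leaves = [root]
    splits = []  # (leaf, feature, threshold, left_leaf, right_leaf)
    tree_nodes = {id(root): {"leaf": root}}
    while len(leaves) < p.num_leaves:
        cand = [lf for lf in leaves if lf.best is not None
                and lf.depth < p.max_depth and lf.best[0] > 0]
        if not cand:
            break
        lf = max(cand, key=lambda l: l.best[0])
        _, j, t = lf.best
        thr = bounds[j][t]
        go_left_full = bins[lf.rows, j] <= t
        go_left_sub = bins[lf.sub, j] <= t
        left = _Leaf(lf.rows[go_left_full], lf.sub[go_left_sub],
                     lf.w[go_left_sub], lf.g[go_left_sub], lf.h[go_left_sub],
                     lf.depth + 1)
        right = _Leaf(lf.rows[~go_left_full], lf.sub[~go_left_sub],
                      lf.w[~go_left_sub], lf.g[~go_left_sub],
                      lf.h[~go_left_sub], lf.depth + 1)
        left.best = _find_best_split(left, bins, bounds, p.min_data_in_leaf)
        right.best = _find_best_split(right, bins, bounds, p.min_data_in_leaf)
        splits.append((lf, j, thr, left, right))
        leaves.remove(lf)
        leaves.extend([left, right])

    # flatten to an array-backed tree usable for routing and serialization
    node_of = {}
    tree = {"feature": [], "threshold": [], "left": [], "right": [],
            "value": [], "count": [], "depth": []}

    def emit(leaf_obj):
        idx = len(tree["feature"])
        node_of[id(leaf_obj)] = idx
        for key in tree:
            tree[key].append(0)
        return idx

    internal = {id(s[0]): s for s in splits}

    def build(nodeobj):
        idx = emit(nodeobj)
        tree["count"][idx] = int(nodeobj.rows.size)
        tree["depth"][idx] = int(nodeobj.depth)
        if id(nodeobj) in internal:
            _, j, thr, left, right = internal[id(nodeobj)]
            tree["feature"][idx] = int(j)
            tree["threshold"][idx] = float(thr)
            tree["left"][idx] = build(left)
            tree["right"][idx] = build(right)
            tree["value"][idx] = np.nan
        else:
            tree["feature"][idx] = -1
            tree["threshold"][idx] = np.nan
            tree["left"][idx] = -1
            tree["right"][idx] = -1
            tree["value"][idx] = _leaf_value(nodeobj)
        return idx

    build(root)
    return {k: np.asarray(v) for k, v in tree.items()}


def _route(tree, X):
    out = np.zeros(X.shape[0])
    for r in range(X.shape[0]):
        idx = 0
        while tree["feature"][idx] >= 0:
            j = tree["feature"][idx]
            idx = (tree["left"][idx] if X[r, j] <= tree["threshold"][idx]
                   else tree["right"][idx])
        out[r] = tree["value"][idx]
    return out


def fit_gbdt(X, y, p: GBDTParams | None = None) -> GBDTModel:
    """Boost NTI rounds of GOSS-sampled, leaf-wise trees on logistic loss."""
    p = p or GBDTParams()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: only one class present")
    if X.shape[0] < 2 * p.min_data_in_leaf:
        raise ValueError("need at least 2*MDL training rows")
    rng = np.random.default_rng(p.seed)
    bins, bounds = _bin_features(X)
    pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    base = float(np.log(pbar / (1 - pbar)))
    F = np.full(X.shape[0], base)
    trees = []
    for _ in range(p.n_iterations):
        prob = 1.0 / (1.0 + np.exp(-F))
        g = prob - y                 # gradient of the logistic loss
        h = prob * (1.0 - prob)
        sub, w = goss_sample(g, p.goss_b, p.goss_c,
                             seed=int(rng.integers(2**31)))
        tree = _grow_tree(X, bins, bounds, g, h, sub, w, p)
        trees.append(tree)
        F = F + p.learning_rate * _route(tree, X)
    return GBDTModel(trees=trees, base_score=base, params=p)


def predict_proba(model: GBDTModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    F = np.full(X.shape[0], model.base_score)
    for tree in model.trees:
        F = F + model.params.learning_rate * _route(tree, X)
    return 1.0 / (1.0 + np.exp(-F))


class GOSSBoostingClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style front end over :func:`fit_gbdt`/:func:`predict_proba`."""

    def __init__(self, min_data_in_leaf=20, n_iterations=100, num_leaves=31,
                 max_depth=6, learning_rate=0.1, goss_b=0.2, goss_c=0.1,
                 random_state=0):
        self.min_data_in_leaf = min_data_in_leaf
        self.n_iterations = n_iterations
        self.num_leaves = num_leaves
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.goss_b = goss_b
        self.goss_c = goss_c
        self.random_state = random_state

    def _params(self) -> GBDTParams:
        return GBDTParams(
            min_data_in_leaf=int(self.min_data_in_leaf),
            n_iterations=int(self.n_iterations),
            num_leaves=int(self.num_leaves),
            max_depth=int(self.max_depth),
            learning_rate=self.learning_rate,
            goss_b=self.goss_b, goss_c=self.goss_c,
            seed=int(self.random_state),
        )

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.model_ = fit_gbdt(X, y, self._params())
        return self

    def predict_proba(self, X):
        p1 = predict_proba(self.model_, X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (predict_proba(self.model_, X) >= 0.5).astype(int)

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))
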