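"""Restricted Boltzmann machines: energies, conditionals, exact partition
functions, and contrastive-divergence training with Adam.

Two unit types are supported: Bernoulli-Bernoulli (BB, binary visibles) and
Gaussian-Bernoulli (GB, real visibles with unit-variance Gaussian energy).
The bipartite energy for BB is

    E(v, h) = - sum_ij W_ij v_i h_j - sum_i a_i v_i - sum_j c_j h_j

with visible biases ``a`` and hidden biases ``c``; the joint distribution is
exp(-E) / Omega with partition function Omega summing exp(-E) over all unit
configurations.  The hidden/visible conditionals are sigmoids of the signed
input plus bias; for GB visibles the conditional is a unit-variance Gaussian
whose mean is the top-down input plus bias.

Exact partition functions (small models only) back the test oracles and the
exact negative log-likelihood monitor used to sanity-check CD training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RBMParams",
    "TrainConfig",
    "sigmoid",
    "energy",
    "cond_hidden",
    "cond_visible",
    "partition_bruteforce",
    "joint_prob",
    "exact_nll",
    "cd_train",
    "init_rbm",
]

_MAX_EXACT_UNITS = 20


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


@dataclass
class RBMParams:
    """Weights and biases of one RBM; ``kind`` is "BB" or "GB"."""

    W: np.ndarray       # n_visible x n_hidden
    b_vis: np.ndarray   # n_visible
    b_hid: np.ndarray   # n_hidden
    kind: str = "BB"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b_vis = np.asarray(self.b_vis, dtype=np.float64)
        self.b_hid = np.asarray(self.b_hid, dtype=np.float64)
        if self.W.shape != (self.b_vis.size, self.b_hid.size):
            raise ValueError("weight/bias shapes are inconsistent")
        if self.kind not in ("BB", "GB"):
            raise ValueError("kind must be 'BB' or 'GB'")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b_vis))
                and np.all(np.isfinite(self.b_hid))):
            raise ValueError("parameters must be finite")

    @property
    def n_visible(self):
        return self.b_vis.size

    @property
    def n_hidden(self):
        return self.b_hid.size


@dataclass
class TrainConfig:
    """CD training settings (Adam optimizer; beta1 = ``momentum``)."""

    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 10
    momentum: float = 0.9
    gradient_decay: float = 0.9
    cd_k: int = 1
    seed: int = 0


def init_rbm(n_visible: int, n_hidden: int, kind: str = "BB",
             scale: float | None = None, seed: int = 0) -> RBMParams:
    """Random initialization; default weight scale 1/sqrt(n_visible) keeps
    initial hidden pre-activations at unit order."""
    rng = np.random.default_rng(seed)
    if scale is None:
        scale = 1.0 / np.sqrt(n_visible)
    return RBMParams(
        W=rng.normal(0.0, scale, (n_visible, n_hidden)),
        b_vis=np.zeros(n_visible),
        b_hid=np.zeros(n_hidden),
        kind=kind,
    )


def energy(v, h, p: RBMParams) -> float:
    """Joint energy of one (visible, hidden) configuration."""
    v = np.asarray(v, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if v.shape != (p.n_visible,) or h.shape != (p.n_hidden,):
        raise ValueError("state shapes do not match the parameters")
    interact = v @ p.W @ h
    if p.kind == "BB":
        if not np.all((v == 0) | (v == 1)):
            raise ValueError("BB visibles must be binary")
        return float(-interact - p.b_vis @ v - p.b_hid @ h)
    # GB: unit-variance Gaussian visible term
    return float(0.5 * np.sum((v - p.b_vis) ** 2) - p.b_hid @ h - interact)


def cond_hidden(v, p: RBMParams) -> np.ndarray:
    """P(h_j = 1 | v) = sigmoid(sum_i v_i W_ij + c_j); rows may batch."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != p.n_visible:
        raise ValueError("visible size mismatch")
    return sigmoid(v @ p.W + p.b_hid)


def cond_visible(h, p: RBMParams) -> np.ndarray:
    """BB: P(v_i = 1 | h); GB: Gaussian mean of v_i given h."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape[-1] != p.n_hidden:
        raise ValueError("hidden size mismatch")
    act = h @ p.W.T + p.b_vis
    return sigmoid(act) if p.kind == "BB" else act


def _all_binary(n: int) -> np.ndarray:
    return ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(np.float64)


def _energy_table(p: RBMParams, V: np.ndarray) -> np.ndarray:
    H = _all_binary(p.n_hidden)
    interact = V @ p.W @ H.T
    if p.kind == "BB":
        return -interact - (V @ p.b_vis)[:, None] - (H @ p.b_hid)[None, :]
    vis = 0.5 * np.sum((V - p.b_vis) ** 2, axis=1)
    return vis[:, None] - interact - (H @ p.b_hid)[None, :]


def _visible_states(p: RBMParams, visible_states=None) -> np.ndarray:
    if p.kind == "GB":
        if visible_states is None:
            raise ValueError("GB partition needs an explicit discretized "
                             "visible state grid")
        return np.asarray(visible_states, dtype=np.float64)
    if visible_states is not None:
        return np.asarray(visible_states, dtype=np.float64)
    return _all_binary(p.n_visible)


def partition_bruteforce(p: RBMParams, visible_states=None) -> float:
    """Omega = sum_{v,h} exp(-E(v,h)) by exhaustive enumeration.

    Refuses models with more than 20 total units (combinatorial guard).  For
    GB models a discretized grid of visible states must be supplied.
    """
    if p.n_visible + p.n_hidden > _MAX_EXACT_UNITS and visible_states is None:
        raise ValueError("too many units for exact enumeration")
    V = _visible_states(p, visible_states)
    return float(np.exp(-_energy_table(p, V)).sum())


def joint_prob(v, h, p: RBMParams, visible_states=None) -> float:
    """exp(-E(v,h)) / Omega."""
    z = partition_bruteforce(p, visible_states)
    return float(np.exp(-energy(v, h, p)) / z)


def exact_nll(p: RBMParams, data: np.ndarray, visible_states=None) -> float:
    """Exact mean negative log-likelihood via the brute-force partition
    function (free energy of each data vector plus log Omega)."""
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    V = _visible_states(p, visible_states)
    z = np.exp(-_energy_table(p, V)).sum()
    # free energy of the data rows
    act = data @ p.W + p.b_hid
    soft = np.logaddexp(0.0, act).sum(axis=1)
    if p.kind == "BB":
        free = -(data @ p.b_vis) - soft
    else:
        free = 0.5 * np.sum((data - p.b_vis) ** 2, axis=1) - soft
    return float(np.mean(free) + np.log(z))


def cd_train(p: RBMParams, data: np.ndarray, cfg: TrainConfig,
             callback=None) -> RBMParams:
    """Train by CD-k with Adam; deterministic for a fixed ``cfg.seed``.

    ``callback(epoch, params)`` (if given) runs after each epoch, e.g. to
    record an exact-NLL trace on tiny models.  GB data is expected to be
    standardized by the caller.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.size == 0:
        raise ValueError("empty training data")
    if data.shape[1] != p.n_visible:
        raise ValueError("data width does not match the visible layer")
    rng = np.random.default_rng(cfg.seed)
    W, a, c = p.W.copy(), p.b_vis.copy(), p.b_hid.copy()
    beta1, beta2, eps = cfg.momentum, 0.999, 1e-8
    m = {k: 0.0 for k in ("W", "a", "c")}
    v2 = {k: 0.0 for k in ("W", "a", "c")}
    step = 0

    def adam(key, grad):
        m[key] = beta1 * m[key] + (1 - beta1) * grad
        v2[key] = beta2 * v2[key] + (1 - beta2) * grad ** 2
        mh = m[key] / (1 - beta1 ** step)
        vh = v2[key] / (1 - beta2 ** step)
        return cfg.learning_rate * mh / (np.sqrt(vh) + eps)

    n = data.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start:start + cfg.batch_size]]
            cur = RBMParams(W, a, c, kind=p.kind)
            ph_pos = cond_hidden(batch, cur)
            vk = batch
            for _ in range(cfg.cd_k):
                h_samp = (rng.random(ph_pos.shape) <
                          cond_hidden(vk, cur)).astype(np.float64)
                vk = cond_visible(h_samp, cur)   # mean-field reconstruction
            ph_neg = cond_hidden(vk, cur)
            b = batch.shape[0]
            gW = (batch.T @ ph_pos - vk.T @ ph_neg) / b
            ga = (batch - vk).mean(axis=0)
            gc = (ph_pos - ph_neg).mean(axis=0)
            step += 1
            W = W + adam("W", gW)
            a = a + adam("a", ga)
            c = c + adam("c", gc)
        if callback is not None:
            callback(epoch, RBMParams(W.copy(), a.copy(), c.copy(), kind=p.kind))
    return RBMParams(W, a, c, kind=p.kind)
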