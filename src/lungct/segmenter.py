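"""Deep-belief-network tumor segmenter.

A Gaussian-Bernoulli RBM is pretrained by contrastive divergence on
standardized image patches and a Bernoulli-Bernoulli RBM on its hidden
activations.  The pretrained stack then initializes a feed-forward network
with a logistic output head, which is fine-tuned by backpropagation on
patch labels (the ground-truth mask value at the patch center) — the
classic greedy-pretrain / supervised-fine-tune recipe for deep belief
networks.  Segmentation slides the patch window across the image at a
fixed stride, writes each patch probability into the central block of the
patch, averages overlapping contributions and thresholds.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .rbm import TrainConfig, cd_train, cond_hidden, init_rbm

__all__ = ["DBNSegmenter", "train_segmenter", "segment", "dice_coefficient"]


def _patch_grid(n: int, patch: int, stride: int) -> np.ndarray:
    """Window origins covering [0, n-patch] at the stride, edge included."""
    starts = list(range(0, n - patch + 1, stride))
    if starts[-1] != n - patch:
        starts.append(n - patch)
    return np.array(starts)


def _extract_patches(img: np.ndarray, patch: int, stride: int):
    ys = _patch_grid(img.shape[0], patch, stride)
    xs = _patch_grid(img.shape[1], patch, stride)
    wins = np.lib.stride_tricks.sliding_window_view(img, (patch, patch))
    tiles = wins[np.ix_(ys, xs)].reshape(len(ys) * len(xs), patch * patch)
    return tiles, ys, xs


class DBNSegmenter(BaseEstimator):
    """Patch classifier built from stacked RBMs, fine-tuned by backprop.

    Parameters
    ----------
    patch_size, stride : int
        Sliding-window geometry used at segmentation time, in pixels.
    train_stride : int
        Denser stride used when harvesting labeled training patches.
    n_hidden_gb, n_hidden_bb : int
        Hidden sizes of the Gaussian-Bernoulli and Bernoulli-Bernoulli RBMs
        (and hence of the fine-tuned network's two hidden layers).
    threshold : float
        Probability cut applied to the assembled per-pixel map.
    assembly_block : int
        Side of the central patch block that receives the patch probability
        during assembly; overlapping contributions are averaged.
    neg_ratio : float
        Background patches kept per tumor patch during training (tumor
        patches are rare; the rest of the background is subsampled).
    max_patches : int
        Hard cap on training patches after rebalancing.
    learning_rate, batch_size, epochs, momentum, cd_k
        Training settings shared by CD pretraining and Adam fine-tuning.
    """

    def __init__(self, patch_size=16, stride=4, train_stride=2,
                 n_hidden_gb=128, n_hidden_bb=64, threshold=0.5,
                 assembly_block=8, neg_ratio=2.0, max_patches=20000,
                 learning_rate=0.001, batch_size=64, epochs=10, momentum=0.9,
                 cd_k=1, random_state=0):
        self.patch_size = patch_size
        self.stride = stride
        self.train_stride = train_stride
        self.n_hidden_gb = n_hidden_gb
        self.n_hidden_bb = n_hidden_bb
        self.threshold = threshold
        self.assembly_block = assembly_block
        self.neg_ratio = neg_ratio
        self.max_patches = max_patches
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.momentum = momentum
        self.cd_k = cd_k
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _harvest(self, images, masks, rng):
        ps = self.patch_size
        X, y = [], []
        for img, mask in zip(images, masks):
            img = np.asarray(img, dtype=np.float64)
            if img.shape[0] < ps or img.shape[1] < ps:
                raise ValueError("image smaller than the patch size")
            tiles, ys, xs = _extract_patches(img, ps, self.train_stride)
            cy = ys[:, None] + ps // 2
            cx = xs[None, :] + ps // 2
            X.append(tiles)
            y.append(np.asarray(mask)[cy, cx].reshape(-1))
        X = np.concatenate(X)
        y = np.concatenate(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("patch labels are all one class; cannot train")
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        n_neg = min(len(neg), max(int(self.neg_ratio * len(pos)), 500))
        neg = rng.choice(neg, size=n_neg, replace=False)
        keep = np.concatenate([pos, neg])
        if len(keep) > self.max_patches:
            keep = rng.choice(keep, size=self.max_patches, replace=False)
        keep.sort()
        return X[keep], y[keep]

    def fit(self, images, masks):
        rng = np.random.default_rng(self.random_state)
        X, y = self._harvest(images, masks, rng)
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0) + 1e-8
        Xs = (X - self.mean_) / self.std_

        def cfg():
            return TrainConfig(learning_rate=self.learning_rate,
                               batch_size=self.batch_size, epochs=self.epochs,
                               momentum=self.momentum, cd_k=self.cd_k,
                               seed=int(rng.integers(2**31)))

        nv = self.patch_size ** 2
        self.rbm_gb_ = cd_train(
            init_rbm(nv, self.n_hidden_gb, kind="GB",
                     seed=int(rng.integers(2**31))), Xs, cfg())
        H1 = cond_hidden(Xs, self.rbm_gb_)
        self.rbm_bb_ = cd_train(
            init_rbm(self.n_hidden_gb, self.n_hidden_bb, kind="BB",
                     seed=int(rng.integers(2**31))), H1, cfg())

        # supervised fine-tuning: the pretrained stack seeds a sigmoid MLP
        # with a logistic output, trained by Adam for `epochs` passes
        mlp = MLPClassifier(
            hidden_layer_sizes=(self.n_hidden_gb, self.n_hidden_bb),
            activation="logistic", solver="adam",
            learning_rate_init=self.learning_rate,
            batch_size=self.batch_size,
            random_state=int(rng.integers(2**31)), max_iter=1)
        i0, i1 = int(np.argmax(y == 0)), int(np.argmax(y == 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny init batch
            mlp.partial_fit(Xs[[i0, i1]], y[[i0, i1]], classes=np.array([0, 1]))
        mlp.coefs_[0] = self.rbm_gb_.W.copy()
        mlp.intercepts_[0] = self.rbm_gb_.b_hid.copy()
        mlp.coefs_[1] = self.rbm_bb_.W.copy()
        mlp.intercepts_[1] = self.rbm_bb_.b_hid.copy()
        for _ in range(self.epochs):
            mlp.partial_fit(Xs, y)
        self.head_ = mlp
        self.n_features_in_ = nv
        return self

    # -------------------------------------------------------------- predict

    def _patch_proba(self, tiles: np.ndarray) -> np.ndarray:
        Xs = (tiles - self.mean_) / self.std_
        return self.head_.predict_proba(Xs)[:, 1]

    def predict_proba_map(self, img) -> np.ndarray:
        """Per-pixel tumor probability assembled from patch probabilities."""
        check_is_fitted(self, "head_")
        img = np.asarray(img, dtype=np.float64)
        ps = self.patch_size
        if img.shape[0] < ps or img.shape[1] < ps:
            raise ValueError("image smaller than the patch size")
        tiles, ys, xs = _extract_patches(img, ps, self.stride)
        probs = self._patch_proba(tiles).reshape(len(ys), len(xs))
        acc = np.zeros(img.shape)
        cnt = np.zeros(img.shape)
        full_acc = np.zeros(img.shape)
        full_cnt = np.zeros(img.shape)
        blk = min(self.assembly_block, ps)
        off = (ps - blk) // 2
        for i, y0 in enumerate(ys):
            for j, x0 in enumerate(xs):
                sl = (slice(y0 + off, y0 + off + blk),
                      slice(x0 + off, x0 + off + blk))
                acc[sl] += probs[i, j]
                cnt[sl] += 1.0
                full = (slice(y0, y0 + ps), slice(x0, x0 + ps))
                full_acc[full] += probs[i, j]
                full_cnt[full] += 1.0
        # pixels missed by the central blocks (image borders) fall back to
        # full-patch coverage
        hole = cnt == 0
        acc[hole] = full_acc[hole]
        cnt[hole] = full_cnt[hole]
        return acc / cnt

    def predict(self, img) -> np.ndarray:
        """Binary tumor mask: probability map thresholded at ``threshold``."""
        return (self.predict_proba_map(img) >= self.threshold).astype(np.uint8)


def train_segmenter(images, masks, **kwargs) -> DBNSegmenter:
    """Fit a :class:`DBNSegmenter`; keyword arguments override its defaults."""
    return DBNSegmenter(**kwargs).fit(images, masks)


def segment(img, model: DBNSegmenter) -> np.ndarray:
    return model.predict(img)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1.0 when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
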