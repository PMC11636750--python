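"""Noise removal and histogram equalization for lung-CT images.

Three denoising filters (plain 3x3 median, k x k average, two-stage adaptive
median) plus CDF-based histogram equalization.  All neighborhood filters use
zero padding at the borders.  The pipeline default is adaptive median
(s_max=7) -> average (k=3) -> equalize.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "average_filter",
    "median_filter3",
    "adaptive_median_filter",
    "histogram_equalize",
    "preprocess_image",
]


def average_filter(img: np.ndarray, k: int = 3) -> np.ndarray:
    """k x k mean filter with zero padding (border means include the zeros)."""
    if k % 2 == 0 or k < 3:
        raise ValueError("kernel size k must be odd and >= 3")
    a = np.asarray(img, dtype=np.float64)
    pad = k // 2
    padded = np.pad(a, pad, mode="constant")
    win = np.lib.stride_tricks.sliding_window_view(padded, (k, k))
    return win.mean(axis=(-2, -1))


def median_filter3(img: np.ndarray) -> np.ndarray:
    """3x3 median with zero padding: each pixel becomes the center of the
    ascending sort of its padded neighborhood."""
    a = np.asarray(img, dtype=np.float64)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    return ndimage.median_filter(a, size=3, mode="constant", cval=0.0)


def adaptive_median_filter(img: np.ndarray, s_max: int = 7) -> np.ndarray:
    """Two-stage adaptive median filter (vectorized over window sizes).

    Stage A grows the window (3, 5, ..., s_max) until the window median is
    not an impulse (min < med < max); stage B then passes the pixel through
    unless the pixel itself is an impulse, in which case the median replaces
    it.  If the window reaches s_max with an impulse median the median at
    s_max is used.
    """
    if s_max % 2 == 0 or s_max < 3:
        raise ValueError("s_max must be odd and >= 3")
    a = np.asarray(img, dtype=np.float64)
    if s_max > min(a.shape):
        raise ValueError("s_max exceeds the image size")
    out = np.empty_like(a)
    undecided = np.ones(a.shape, dtype=bool)
    zmed = a
    for s in range(3, s_max + 1, 2):
        zmin = ndimage.minimum_filter(a, size=s, mode="constant", cval=0.0)
        zmax = ndimage.maximum_filter(a, size=s, mode="constant", cval=0.0)
        zmed = ndimage.median_filter(a, size=s, mode="constant", cval=0.0)
        stage_a = (zmin < zmed) & (zmed < zmax)
        done = undecided & stage_a
        keep = (zmin < a) & (a < zmax)          # stage B: pixel not an impulse
        out[done & keep] = a[done & keep]
        out[done & ~keep] = zmed[done & ~keep]
        undecided &= ~stage_a
    out[undecided] = zmed[undecided]
    return out


def _round_half_down(x: np.ndarray) -> np.ndarray:
    # nearest integer, exact halves rounded down (127.5 -> 127)
    return np.ceil(np.asarray(x) - 0.5).astype(np.int64)


def histogram_equalize(img: np.ndarray, n_levels: int = 256) -> np.ndarray:
    """Histogram equalization through the image's own CDF.

    Level frequencies are normalized to probabilities P(k) = n_k / n, the CDF
    is their cumulative sum, and level k maps to round(CDF(k) * (N-1)); the
    mapping stretches the output across the full [0, N-1] range.  Float
    images in [0, 1] are quantized to ``n_levels`` gray levels first.
    """
    a = np.asarray(img)
    if a.size == 0:
        raise ValueError("empty image")
    if n_levels < 2:
        raise ValueError("need at least two gray levels")
    was_float = np.issubdtype(a.dtype, np.floating)
    if was_float:
        levels = _round_half_down(np.clip(a, 0.0, 1.0) * (n_levels - 1))
    else:
        levels = a.astype(np.int64)
        if levels.min() < 0 or levels.max() >= n_levels:
            raise ValueError("integer image values must lie in [0, N-1]")
    counts = np.bincount(levels.ravel(), minlength=n_levels)
    p = counts / levels.size
    cdf = np.cumsum(p)
    mapping = _round_half_down(cdf * (n_levels - 1))
    out = mapping[levels]
    if was_float:
        return out.astype(np.float64) / (n_levels - 1)
    return out.astype(np.uint8 if n_levels <= 256 else np.int64)


def level_probabilities(img: np.ndarray, n_levels: int = 256) -> np.ndarray:
    """P(k) = n_k / n for each gray level k (sums to 1)."""
    a = np.asarray(img)
    if np.issubdtype(a.dtype, np.floating):
        a = _round_half_down(np.clip(a, 0.0, 1.0) * (n_levels - 1))
    counts = np.bincount(a.ravel().astype(np.int64), minlength=n_levels)
    return counts / a.size


def preprocess_image(img: np.ndarray, s_max: int = 7, k: int = 3,
                     equalize: bool = True) -> np.ndarray:
    """Default chain: adaptive median -> average -> histogram equalization."""
    out = adaptive_median_filter(img, s_max=s_max)
    out = average_filter(out, k=k)
    if equalize:
        out = histogram_equalize(out)
    return out
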