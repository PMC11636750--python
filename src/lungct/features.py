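"""Fixed 50-feature catalogue extracted from a segmented image region.

The catalogue (frozen; see ``FEATURE_NAMES``):

* 5 first-order moments of the region intensities (mean, variance, standard
  deviation, third-moment skewness, fourth-moment excess kurtosis),
* 5 of the same moments over the whole image,
* 16-bin normalized intensity histogram of the region,
* 8 shape descriptors of the region mask (area fraction, perimeter,
  eccentricity, solidity, extent, major/minor axis length, compactness),
* 8 gray-level co-occurrence statistics of the region bounding box,
* 8 gradient/edge statistics (Sobel magnitude inside the region and over
  the whole image).

All moments are population moments; a degenerate (zero-variance) region has
skewness and kurtosis reported as 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure
from skimage.feature import graycomatrix
from skimage.filters import sobel

__all__ = ["FEATURE_NAMES", "first_order_stats", "extract_feature_vector",
           "build_feature_table"]

N_HIST_BINS = 16
N_GLCM_LEVELS = 32

FEATURE_NAMES = (
    ["region_mean", "region_variance", "region_std", "region_skewness",
     "region_kurtosis",
     "image_mean", "image_variance", "image_std", "image_skewness",
     "image_kurtosis"]
    + [f"region_hist_bin{i:02d}" for i in range(N_HIST_BINS)]
    + ["shape_area_fraction", "shape_perimeter", "shape_eccentricity",
       "shape_solidity", "shape_extent", "shape_major_axis",
       "shape_minor_axis", "shape_compactness"]
    + ["glcm_contrast", "glcm_dissimilarity", "glcm_homogeneity", "glcm_asm",
       "glcm_energy", "glcm_correlation", "glcm_entropy", "glcm_max_prob"]
    + ["grad_region_mean", "grad_region_std", "grad_region_max",
       "grad_region_p90", "grad_image_mean", "grad_image_std",
       "edge_density_region", "edge_density_image"]
)
assert len(FEATURE_NAMES) == 50


def first_order_stats(pixels) -> tuple:
    """Population (mean, variance, std, skewness, excess kurtosis)."""
    x = np.asarray(pixels, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty pixel list")
    mu = x.mean()
    d = x - mu
    m2 = np.mean(d ** 2)
    if m2 < 1e-24:
        return float(mu), float(m2), float(np.sqrt(m2)), 0.0, 0.0
    m3 = np.mean(d ** 3)
    m4 = np.mean(d ** 4)
    skew = m3 / m2 ** 1.5
    kurt = m4 / m2 ** 2 - 3.0
    return float(mu), float(m2), float(np.sqrt(m2)), float(skew), float(kurt)


def _glcm_stats(img: np.ndarray, mask: np.ndarray) -> list:
    """Co-occurrence statistics on the region bounding box (distance 1,
    horizontal offset, symmetric, normalized); outside-mask pixels are set
    to level 0 before quantization."""
    ys, xs = np.nonzero(mask)
    box = img[ys.min():ys.max() + 1, xs.min():xs.max() + 1].copy()
    boxmask = mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    box = np.where(boxmask, box, 0.0)
    q = np.clip((box * (N_GLCM_LEVELS - 1)).round().astype(np.uint8), 0,
                N_GLCM_LEVELS - 1)
    if q.shape[1] < 2:  # single-column region: no horizontal pairs
        q = np.pad(q, ((0, 0), (0, 1)))
    P = graycomatrix(q, [1], [0], levels=N_GLCM_LEVELS, symmetric=True,
                     normed=True)[:, :, 0, 0]
    i, j = np.mgrid[0:N_GLCM_LEVELS, 0:N_GLCM_LEVELS]
    contrast = float(np.sum(P * (i - j) ** 2))
    dissim = float(np.sum(P * np.abs(i - j)))
    homog = float(np.sum(P / (1.0 + (i - j) ** 2)))
    asm = float(np.sum(P ** 2))
    energ = float(np.sqrt(asm))
    mu_i = np.sum(i * P)
    mu_j = np.sum(j * P)
    sd_i = np.sqrt(np.sum((i - mu_i) ** 2 * P))
    sd_j = np.sqrt(np.sum((j - mu_j) ** 2 * P))
    if sd_i * sd_j < 1e-15:
        corr = 1.0
    else:
        corr = float(np.sum((i - mu_i) * (j - mu_j) * P) / (sd_i * sd_j))
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return [contrast, dissim, homog, asm, energ, corr, entropy,
            float(P.max())]


def _shape_stats(mask: np.ndarray) -> list:
    # the whole foreground is treated as one (possibly disconnected) region
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(mask.sum())
    perim = float(props.perimeter)
    compact = 4.0 * np.pi * area / perim ** 2 if perim > 0 else 0.0
    return [area / mask.size, perim, float(props.eccentricity),
            float(props.solidity), float(props.extent),
            float(props.axis_major_length), float(props.axis_minor_length),
            compact]


def extract_feature_vector(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The frozen 50-feature vector for one image/region pair.

    Pure function of its inputs; raises on an empty mask rather than
    emitting silent zeros.
    """
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask: no segmented region to describe")

    region = img[mask]
    feats = list(first_order_stats(region))
    feats += list(first_order_stats(img))
    hist, _ = np.histogram(region, bins=N_HIST_BINS, range=(0.0, 1.0))
    feats += list(hist / region.size)
    feats += _shape_stats(mask)
    feats += _glcm_stats(img, mask)

    g = sobel(img)
    gr = g[mask]
    feats += [float(gr.mean()), float(gr.std()), float(gr.max()),
              float(np.percentile(gr, 90)), float(g.mean()), float(g.std()),
              float(np.mean(gr > 0.1)), float(np.mean(g > 0.1))]
    out = np.asarray(feats, dtype=np.float64)
    if out.size != 50 or not np.all(np.isfinite(out)):
        raise AssertionError("feature vector must be 50 finite values")
    return out


def build_feature_table(images, masks, labels) -> pd.DataFrame:
    """Stack feature vectors into a table with named columns plus ``label``."""
    rows = [extract_feature_vector(i, m) for i, m in zip(images, masks)]
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    df["label"] = np.asarray(labels, dtype=int)
    return df
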