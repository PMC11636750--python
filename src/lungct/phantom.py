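"""Synthetic lung-CT-like phantoms with ground-truth tumor masks and labels.

The generator draws a soft-tissue background with two dark elliptical lung
fields and plants bright tumor blobs (disks/ellipses) inside them, then
corrupts the image with Gaussian noise followed by salt-and-pepper impulses.
Every sample carries a pixel-aligned binary mask (the tumor region) and a
binary image-level label: *cancer* iff at least one tumor was planted.

Only statistical separability matters here — the phantoms exist so the
segmentation, feature-extraction and classification stages can be exercised
and tested without any external CT data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "Dataset",
    "generate_phantom",
    "add_noise",
    "generate_dataset",
    "REFERENCE_SPLIT_COUNTS",
    "reference_split_design",
]

# Class-by-split image counts of the CT study design the benchmark emulates:
# rows = (train, validation, test).
REFERENCE_SPLIT_COUNTS = {
    "non_cancer": (2891, 2166, 2403),
    "cancer": (2145, 2845, 2955),
}

# intensity palette (arbitrary units in [0, 1])
_BODY = 0.55
_LUNG = 0.20


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise settings of one phantom image.

    ``lung_ellipses`` lists ``(cy, cx, semi_a, semi_b)`` in relative [0, 1]
    coordinates; tumors are rejected if a blob of the drawn radius cannot fit
    entirely inside a lung ellipse.  ``tumor_intensity`` is the contrast added
    on top of the lung-field gray, kept in the +0.2..+0.5 band by default.
    """

    height: int = 240
    width: int = 240
    lung_ellipses: tuple = (
        (0.50, 0.30, 0.32, 0.17),
        (0.50, 0.70, 0.32, 0.17),
    )
    tumor_count: int = 1
    tumor_radius_range: tuple = (8, 24)
    tumor_intensity: tuple = (0.2, 0.5)
    tumor_aspect_range: tuple = (0.7, 1.0)
    gaussian_sigma: float = 0.03
    sp_density: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom dimensions must be >= 32 pixels")
        if not (0.0 <= self.sp_density <= 1.0):
            raise ValueError("sp_density must lie in [0, 1]")
        if self.tumor_count < 0:
            raise ValueError("tumor_count must be >= 0")
        lo, hi = self.tumor_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("tumor_radius_range must be positive and ordered")

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PhantomSample:
    image: np.ndarray  # float64 in [0, 1], H x W
    mask: np.ndarray   # uint8 {0, 1}, H x W
    label: int         # 1 = cancer, 0 = non-cancer
    tumors: list = field(default_factory=list)  # (cy, cx, r, aspect, theta)


@dataclass
class Dataset:
    samples: list
    split: dict  # {"train": [...], "validation": [...], "test": [...]}

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def indices(self, part: str) -> list:
        return self.split[part]


def _ellipse_mask(h, w, cy, cx, a, b, yy=None, xx=None):
    if yy is None:
        yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def _place_tumor(rng, cfg, lungs_abs, r):
    """Pick a center so a blob of radius ``r`` fits inside one lung ellipse."""
    for _ in range(200):
        cy0, cx0, a, b = lungs_abs[rng.integers(len(lungs_abs))]
        if r >= min(a, b):
            continue
        # shrink the ellipse by r: any center inside it keeps the disk inside
        u, v = rng.uniform(-1, 1, 2)
        if u * u + v * v > 1:
            continue
        return cy0 + u * (a - r), cx0 + v * (b - r)
    raise ValueError(
        f"tumor of radius {r} does not fit inside the configured lung field"
    )


def generate_phantom(cfg: PhantomConfig, seed: int | None = None) -> PhantomSample:
    """Render one phantom; deterministic for a given ``cfg`` and ``seed``."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    h, w = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), _BODY, dtype=np.float64)

    lungs_abs = []
    for (cy, cx, a, b) in cfg.lung_ellipses:
        cy, cx, a, b = cy * h, cx * w, a * h, b * w
        lungs_abs.append((cy, cx, a, b))
        img[_ellipse_mask(h, w, cy, cx, a, b, yy, xx)] = _LUNG

    mask = np.zeros((h, w), dtype=np.uint8)
    tumors = []
    for _ in range(cfg.tumor_count):
        r = rng.uniform(*cfg.tumor_radius_range)
        cy, cx = _place_tumor(rng, cfg, lungs_abs, r)
        aspect = rng.uniform(*cfg.tumor_aspect_range)
        theta = rng.uniform(0, np.pi)
        contrast = rng.uniform(*cfg.tumor_intensity)
        tumors.append((cy, cx, r, aspect, theta))
        # rotated ellipse with semi-axes (r, aspect*r); circle when aspect=1
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        blob = (u / r) ** 2 + (v / (aspect * r)) ** 2 <= 1.0
        img[blob] = np.clip(_LUNG + contrast, 0.0, 1.0)
        mask[blob] = 1

    img = add_noise(
        img,
        sigma=cfg.gaussian_sigma,
        sp_density=cfg.sp_density,
        seed=int(rng.integers(2**31)),
    )
    label = 1 if cfg.tumor_count >= 1 else 0
    return PhantomSample(image=img, mask=mask, label=label, tumors=tumors)


def add_noise(img: np.ndarray, sigma: float, sp_density: float,
              seed: int = 0) -> np.ndarray:
    """Gaussian noise (added, then clipped to [0,1]) followed by
    salt-and-pepper impulses, so true impulse extremes survive for the
    median-filter stage to remove.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not (0.0 <= sp_density <= 1.0):
        raise ValueError("sp_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.asarray(img, dtype=np.float64)
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, out.shape)
    out = np.clip(out, 0.0, 1.0)
    if sp_density > 0:
        hit = rng.random(out.shape) < sp_density
        salt = rng.random(out.shape) < 0.5
        out = out.copy()
        out[hit & salt] = 1.0
        out[hit & ~salt] = 0.0
    return out


def _largest_remainder(total: int, fracs: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``fracs`` (sums exactly)."""
    raw = np.asarray(fracs, dtype=float) * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_dataset(n: int, prevalence: float, split_fracs,
                     cfg: PhantomConfig | None = None,
                     seed: int = 0) -> Dataset:
    """Generate ``n`` labeled phantoms with stratified train/val/test splits.

    ``split_fracs`` is either one (train, val, test) triple applied to both
    classes or a ``{0: triple, 1: triple}`` dict giving per-class fractions
    (used to emulate the reference study's split structure).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    cfg = cfg or PhantomConfig()
    if isinstance(split_fracs, dict):
        per_class = {k: np.asarray(v, float) for k, v in split_fracs.items()}
    else:
        f = np.asarray(split_fracs, float)
        per_class = {0: f, 1: f}
    for f in per_class.values():
        if not np.isclose(f.sum(), 1.0):
            raise ValueError("split fractions must sum to 1")

    n_cancer = int(round(n * prevalence))
    labels = np.array([1] * n_cancer + [0] * (n - n_cancer))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    samples = []
    for lab in labels:
        tc = max(cfg.tumor_count, 1) if lab == 1 else 0
        sub = cfg.replace(tumor_count=tc)
        samples.append(generate_phantom(sub, seed=int(rng.integers(2**31))))

    split = {"train": [], "validation": [], "test": []}
    for lab in (0, 1):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        counts = _largest_remainder(len(idx), per_class[lab])
        pos = 0
        for part, c in zip(("train", "validation", "test"), counts):
            split[part].extend(int(i) for i in idx[pos:pos + c])
            pos += c
    for part in split:
        split[part].sort()
    return Dataset(samples=samples, split=split)


def reference_split_design():
    """Prevalence and per-class split fractions matching the reference
    class-by-split image counts (see ``REFERENCE_SPLIT_COUNTS``)."""
    nc = np.array(REFERENCE_SPLIT_COUNTS["non_cancer"], float)
    ca = np.array(REFERENCE_SPLIT_COUNTS["cancer"], float)
    prevalence = ca.sum() / (ca.sum() + nc.sum())
    return prevalence, {0: nc / nc.sum(), 1: ca / ca.sum()}
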