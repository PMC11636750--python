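"""End-to-end orchestration: phantom generation -> preprocessing ->
DBN segmentation -> feature extraction -> spiral/rough-set selection ->
Harris-hawks-tuned GOSS boosting -> evaluation.

Every stage except classification can be toggled off for ablation studies.
All randomness is derived from a single seed, so a re-run with the same
configuration reproduces the report bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import phantom as ph
from .boosting import GBDTParams, GOSSBoostingClassifier
from .features import FEATURE_NAMES, build_feature_table
from .hho import tune
from .metrics import compute_metrics, confusion_from_predictions, roc_curve
from .preprocess import preprocess_image
from .segmenter import DBNSegmenter, dice_coefficient
from .selection import SpiralRoughSetSelector

__all__ = ["PipelineConfig", "EvalReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage toggles and benchmark settings (classification is always on)."""

    n_samples: int = 400
    prevalence: float = 0.5
    split_fracs: tuple = (0.5, 0.2, 0.3)
    image_size: int = 64
    tumor_radius_range: tuple = (4, 9)
    seed: int = 7
    preprocess: bool = True
    segmentation: bool = True
    feature_selection: bool = True
    hyperparam_opt: bool = True
    # stage settings
    segmenter_kwargs: dict = field(default_factory=dict)
    selector_kwargs: dict = field(default_factory=dict)
    tune_kwargs: dict = field(default_factory=lambda: {"n_hawks": 5, "T": 6})
    default_params: dict = field(default_factory=dict)


@dataclass
class EvalReport:
    confusion: dict
    metrics: dict
    auc: float
    roc_points: list
    mean_dice: float
    n_selected: int
    selected_features: list
    params: dict
    stage_seconds: dict
    seed: int

    def to_json(self, include_timing: bool = False, **kw) -> str:
        """Canonical JSON form; wall-clock timings are excluded by default
        so identical seeds yield byte-identical reports."""
        d = asdict(self)
        if not include_timing:
            d.pop("stage_seconds")
        return json.dumps(d, sort_keys=True, **kw)


def _phantom_cfg(cfg: PipelineConfig) -> ph.PhantomConfig:
    return ph.PhantomConfig(height=cfg.image_size, width=cfg.image_size,
                            tumor_radius_range=cfg.tumor_radius_range)


def run_pipeline(cfg: PipelineConfig | None = None) -> EvalReport:
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(rng.integers(2**31))
             for k in ("data", "segmenter", "selector", "tuner", "final")}
    timer: dict = {}

    def tic(stage):
        timer[stage] = time.perf_counter()

    def toc(stage):
        timer[stage] = round(time.perf_counter() - timer[stage], 3)

    tic("generate")
    ds = ph.generate_dataset(cfg.n_samples, cfg.prevalence, cfg.split_fracs,
                             cfg=_phantom_cfg(cfg), seed=seeds["data"])
    labels = ds.labels
    toc("generate")

    tic("preprocess")
    if cfg.preprocess:
        images = [preprocess_image(s.image) for s in ds.samples]
    else:
        images = [s.image for s in ds.samples]
    toc("preprocess")

    tr = ds.indices("train")
    va = ds.indices("validation")
    te = ds.indices("test")

    tic("segmentation")
    mean_dice = float("nan")
    if cfg.segmentation:
        seg = DBNSegmenter(random_state=seeds["segmenter"],
                           **cfg.segmenter_kwargs)
        seg.fit([images[i] for i in tr], [ds.samples[i].mask for i in tr])
        pred_masks = [seg.predict(img) for img in images]
        dices = [dice_coefficient(pred_masks[i], ds.samples[i].mask)
                 for i in te if ds.samples[i].mask.any()]
        mean_dice = float(np.mean(dices)) if dices else float("nan")
    else:
        pred_masks = [np.ones_like(ds.samples[i].mask)
                      for i in range(len(ds.samples))]
    toc("segmentation")

    tic("features")
    # empty predicted masks (typically non-cancer images) fall back to the
    # whole-image region so the 50-feature vector stays well defined
    regions = [m if m.any() else np.ones_like(m) for m in pred_masks]
    table = build_feature_table(images, regions, labels)
    X = table[list(FEATURE_NAMES)].to_numpy()
    toc("features")

    tic("selection")
    if cfg.feature_selection:
        sel = SpiralRoughSetSelector(random_state=seeds["selector"],
                                     **cfg.selector_kwargs)
        sel.fit(X[tr], labels[tr])
        support = sel.get_support()
    else:
        support = np.ones(X.shape[1], dtype=bool)
    Xs = X[:, support]
    selected = [n for n, s in zip(FEATURE_NAMES, support) if s]
    toc("selection")

    tic("tuning")
    if cfg.hyperparam_opt:
        params = tune(Xs[tr], labels[tr], seed=seeds["tuner"],
                      **cfg.tune_kwargs)
    else:
        params = GBDTParams(seed=seeds["tuner"], **cfg.default_params)
    toc("tuning")

    tic("classification")
    fit_idx = sorted(tr + va)  # tuning used CV on train; final fit adds val
    # small benchmark runs cap MDL at half the fit rows so the root can split
    mdl = min(params.min_data_in_leaf, max(1, len(fit_idx) // 2))
    clf = GOSSBoostingClassifier(
        min_data_in_leaf=mdl,
        n_iterations=params.n_iterations, num_leaves=params.num_leaves,
        max_depth=params.max_depth, learning_rate=params.learning_rate,
        goss_b=params.goss_b, goss_c=params.goss_c,
        random_state=seeds["final"])
    clf.fit(Xs[fit_idx], labels[fit_idx])
    scores = clf.predict_proba(Xs[te])[:, 1]
    y_pred = (scores >= 0.5).astype(int)
    toc("classification")

    cm = confusion_from_predictions(labels[te], y_pred)
    mets = compute_metrics(cm)
    points, auc = roc_curve(scores, labels[te])
    return EvalReport(
        confusion={"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        metrics={k: v for k, v in mets.items() if k != "undefined"},
        auc=auc,
        roc_points=points.tolist(),
        mean_dice=mean_dice,
        n_selected=int(np.sum(support)),
        selected_features=selected,
        params={"min_data_in_leaf": params.min_data_in_leaf,
                "n_iterations": params.n_iterations,
                "num_leaves": params.num_leaves,
                "max_depth": params.max_depth},
        stage_seconds=timer,
        seed=cfg.seed,
    )
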