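"""Confusion-matrix metrics and ROC analysis for the binary cancer task.

Positive class = cancer = label 1 throughout.  Zero-denominator ratios are
reported as 0 and flagged rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from sklearn import metrics as skm

__all__ = ["ConfusionMatrix", "compute_metrics", "roc_curve",
           "confusion_from_predictions"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix, exact: bool = False) -> dict:
    """Accuracy, sensitivity/recall, specificity, precision and F-measure.

    With ``exact=True`` the ratios are returned as :class:`Fraction` (no
    floating-point rounding); degenerate denominators are listed under
    ``"undefined"`` and reported as 0.
    """
    flags: list = []
    div = (lambda a, b, n: Fraction(a, b) if b else (flags.append(n) or
                                                     Fraction(0))) \
        if exact else (lambda a, b, n: _ratio(a, b, flags, n))
    acc = div(cm.tp + cm.tn, cm.total, "accuracy")
    sens = div(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = div(cm.tn, cm.tn + cm.fp, "specificity")
    prec = div(cm.tp, cm.tp + cm.fp, "precision")
    rec = sens
    if prec + rec == 0:
        flags.append("f_measure")
        f1 = Fraction(0) if exact else 0.0
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "precision": prec, "recall": rec, "f_measure": f1,
            "undefined": sorted(set(flags))}


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_curve(scores, labels):
    """(FPR, TPR) staircase over all distinct score thresholds, plus the
    trapezoid AUC.  Tied scores enter simultaneously."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = skm.roc_curve(labels, np.asarray(scores, float),
                                drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc
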