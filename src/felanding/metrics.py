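"""Confusion-matrix metrics for the two-class landing-height classifiers.

Nine measures are computed from a single 2x2 confusion matrix: accuracy,
sensitivity (recall), specificity, precision, F1, TPR, FPR, single-point AUC
and the Matthews correlation coefficient (MCC).  The AUC here is the
one-operating-point formula (TPR - FPR + 1) / 2 — algebraically the mean of
sensitivity and specificity (balanced accuracy), *not* the trapezoidal area
under a swept ROC curve; :func:`roc_curve` provides the threshold-swept
staircase and its trapezoidal area separately for comparison.

Zero denominators never silently become 0: the affected metric is NaN and its
name appears in ``MetricsBundle.undefined``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 tally: TP/FN from the actual positives, TN/FP from the negatives."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ConfigurationError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def actual_positives(self) -> int:
        return self.tp + self.fn

    @property
    def actual_negatives(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricsBundle:
    """The nine measures; undefined ones are NaN and listed in ``undefined``."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    tpr: float
    fpr: float
    auc: float
    mcc: float
    undefined: list[str] = field(default_factory=list)

    def as_report(self) -> dict[str, str]:
        """Rates as percentages to 2 decimals, proportions to 4 (the raw
        full-precision values stay on the bundle itself)."""
        pct = lambda v: "undefined" if math.isnan(v) else f"{100 * v:.2f}%"
        prop = lambda v: "undefined" if math.isnan(v) else f"{v:.4f}"
        return {
            "accuracy": pct(self.accuracy),
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "precision": pct(self.precision),
            "f1": prop(self.f1),
            "tpr": prop(self.tpr),
            "fpr": prop(self.fpr),
            "auc": prop(self.auc),
            "mcc": prop(self.mcc),
        }


def from_predictions(y_true, y_pred, positive=1) -> ConfusionMatrix:
    """Exhaustive, mutually exclusive tally of a binary prediction run."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ConfigurationError("label sequences must have equal length")
    classes = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(classes - {positive}) > 1:
        raise ConfigurationError(
            f"labels {sorted(classes, key=str)} are not binary around positive={positive}")
    p_true = y_true == positive
    p_pred = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(p_true & p_pred)),
        fn=int(np.sum(p_true & ~p_pred)),
        tn=int(np.sum(~p_true & ~p_pred)),
        fp=int(np.sum(~p_true & p_pred)),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricsBundle:
    """All nine measures from the printed closed-form definitions."""
    if cm.total == 0:
        raise ConfigurationError("empty confusion matrix")
    tp, fn, tn, fp = float(cm.tp), float(cm.fn), float(cm.tn), float(cm.fp)
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = (tp + tn) / (tp + fn + fp + tn)
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, fp + tn, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if math.isnan(sensitivity) or math.isnan(precision) or precision + sensitivity == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    tpr = sensitivity
    fpr = ratio(fp, fp + tn, "fpr")
    if math.isnan(tpr) or math.isnan(fpr):
        undefined.append("auc")
        auc = float("nan")
    else:
        auc = (tpr - fpr + 1) / 2
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined.append("mcc")
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    # sensitivity doubles as tpr; report it under both names but flag once each
    if math.isnan(sensitivity) and "tpr" not in undefined:
        undefined.append("tpr")
    return MetricsBundle(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, precision=precision, f1=f1,
                         tpr=tpr, fpr=fpr, auc=auc, mcc=mcc, undefined=undefined)


def roc_curve(scores, y_true, positive=1) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-swept ROC staircase and its trapezoidal area.

    Returns (fpr, tpr, area): a monotone staircase from (0, 0) to (1, 1).
    The area is the swept-curve integral — deliberately distinct from the
    single-point AUC of :func:`compute_metrics`.  Ties in the scores collapse
    into single sweep steps.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.shape != y_true.shape:
        raise ConfigurationError("scores and labels must align")
    pos = y_true == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    # keep only the last point of each tied-score run
    distinct = np.append(np.diff(sorted_scores) != 0, True)
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area
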