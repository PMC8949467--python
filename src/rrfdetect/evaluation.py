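"""Binary-classification evaluation: confusion matrix, the eight summary
metrics, ROC curves and AUC.

Metric conventions: SEN = TP/(TP+FN), SPE = TN/(TN+FP), FPR = FP/(FP+TN),
FNR = FN/(FN+TP), PPV = TP/(TP+FP), NPV = TN/(TN+FN), ACC = (TP+TN)/N and
F1 = 2TP/(2TP+FP+FN).  A ratio with a zero denominator is reported as 0
and flagged as degenerate rather than raising, so batch evaluation over
many folds never aborts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

METRIC_NAMES = ("sen", "spe", "fpr", "fnr", "ppv", "npv", "acc", "f1")


@dataclass
class ConfusionMatrix:
    """Counts for one binary problem; rows = true class, columns = predicted."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive: str

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sen: float
    spe: float
    fpr: float
    fnr: float
    ppv: float
    npv: float
    acc: float
    f1: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class ROCCurve:
    """Threshold-swept ROC points, sorted by (FPR, TPR), with trapezoidal
    AUC.  The AUC equals the Mann-Whitney probability that a random
    positive outscores a random negative, with ties counted 1/2."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    positive: str = ""


def confusion(
    labels: Sequence[str], predictions: Sequence[str], positive: str
) -> ConfusionMatrix:
    """Exact confusion counts for a two-class label/prediction pairing."""
    y = np.asarray(labels)
    yhat = np.asarray(predictions)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {yhat.shape} predictions")
    classes = set(y) | set(yhat)
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} absent from {sorted(classes)}")
    if len(classes) > 2:
        raise ValueError(f"more than two classes present: {sorted(classes)}")
    pos_true = y == positive
    pos_pred = yhat == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_true & pos_pred)),
        fp=int(np.sum(~pos_true & pos_pred)),
        tn=int(np.sum(~pos_true & ~pos_pred)),
        fn=int(np.sum(pos_true & ~pos_pred)),
        positive=positive,
    )


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The eight summary metrics of one confusion matrix."""
    if cm.total < 1:
        raise ValueError("confusion matrix has no observations")
    degenerate: list[str] = []
    return MetricsReport(
        sen=_ratio(cm.tp, cm.tp + cm.fn, "sen", degenerate),
        spe=_ratio(cm.tn, cm.tn + cm.fp, "spe", degenerate),
        fpr=_ratio(cm.fp, cm.fp + cm.tn, "fpr", degenerate),
        fnr=_ratio(cm.fn, cm.fn + cm.tp, "fnr", degenerate),
        ppv=_ratio(cm.tp, cm.tp + cm.fp, "ppv", degenerate),
        npv=_ratio(cm.tn, cm.tn + cm.fn, "npv", degenerate),
        acc=(cm.tp + cm.tn) / cm.total,
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1", degenerate),
        degenerate=tuple(degenerate),
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[str], positive: str
) -> ROCCurve:
    """ROC curve by threshold sweep and its trapezoidal AUC."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    is_pos = y == positive
    if is_pos.all() or not is_pos.any():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(is_pos.astype(int), s, drop_intermediate=False)
    order = np.lexsort((tpr, fpr))
    fpr, tpr, thr = fpr[order], tpr[order], thr[order]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, positive=positive)
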