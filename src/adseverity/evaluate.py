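"""Confusion-matrix and ROC reporting for the four severity classes.

Per-class sensitivity (recall, diagonal over true-class row sum) and
precision (diagonal over predicted-class column sum) follow the usual
confusion-matrix layout with rows = true class and columns = predicted
class, classes ordered (low, mild, moderate, severe).  Classes with no
true (resp. predicted) members get an undefined (NaN) entry rather than
a silent zero.  ROC curves are one-vs-rest with trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .mmse import CLASS_NAMES

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "confusion",
    "sensitivity",
    "precision",
    "accuracy",
    "roc_one_vs_rest",
    "macro_auc",
    "evaluation_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # K x K int, rows = true, cols = predicted
    class_names: tuple[str, ...] = CLASS_NAMES

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion(true_labels, predicted_labels, n_classes: int = 4) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(predicted_labels, dtype=int).ravel()
    if t.size == 0 or t.size != p.size:
        raise ValueError("label lists must be aligned and nonempty")
    if np.any((t < 0) | (t >= n_classes)) or np.any((p < 0) | (p >= n_classes)):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, CLASS_NAMES[:n_classes])


def sensitivity(matrix: ConfusionMatrix) -> np.ndarray:
    """Per-class recall; NaN where a class has no true members."""
    c = matrix.counts
    row = c.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.diag(c) / np.where(row == 0, np.nan, row)
    return out


def precision(matrix: ConfusionMatrix) -> np.ndarray:
    """Per-class positive predictive value; NaN where a class is never predicted."""
    c = matrix.counts
    col = c.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.diag(c) / np.where(col == 0, np.nan, col)
    return out


def accuracy(matrix: ConfusionMatrix) -> float:
    """Overall accuracy: trace over total count."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(matrix.counts) / matrix.total)


def roc_one_vs_rest(class_scores, true_labels, positive_class: int) -> RocCurve:
    """ROC treating ``positive_class`` vs the rest; AUC by the trapezoid rule.

    ``class_scores`` is either the per-sample score for the positive
    class, or a samples x classes score matrix from which that column is
    taken.  Tied scores collapse into single threshold steps.
    """
    t = np.asarray(true_labels, dtype=int).ravel()
    scores = np.asarray(class_scores, dtype=float)
    if scores.ndim == 2:
        scores = scores[:, int(positive_class)]
    if scores.size != t.size:
        raise ValueError("scores and labels must be aligned")
    pos = t == int(positive_class)
    if not pos.any():
        raise ValueError(f"positive class {positive_class} absent from true labels")
    fpr, tpr, thresholds = _sk_roc_curve(pos.astype(int), scores)
    return RocCurve(thresholds, fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


def macro_auc(class_scores, true_labels, n_classes: int = 4) -> float:
    """Unweighted mean of the one-vs-rest AUCs over the classes present."""
    t = np.asarray(true_labels, dtype=int).ravel()
    aucs = [roc_one_vs_rest(class_scores, t, c).auc
            for c in range(n_classes) if np.any(t == c)]
    return float(np.mean(aucs))


def _pct(x: float) -> float | None:
    return None if np.isnan(x) else round(100.0 * x, 1)


def evaluation_report(true_labels, predicted_labels, class_scores=None) -> dict:
    """Bundle the published reporting layout into one JSON-friendly dict.

    Percentages are rounded to one decimal; undefined per-class entries
    (a class with no members) appear as None ("n/a"), never as 0.
    """
    cm = confusion(true_labels, predicted_labels)
    report = {
        "confusion_matrix": cm.counts.tolist(),
        "class_order": list(cm.class_names),
        "sensitivity_pct": [_pct(v) for v in sensitivity(cm)],
        "precision_pct": [_pct(v) for v in precision(cm)],
        "accuracy_pct": round(100.0 * accuracy(cm), 1),
    }
    if class_scores is not None:
        t = np.asarray(true_labels, dtype=int)
        report["auc"] = [
            round(roc_one_vs_rest(class_scores, t, c).auc, 4) if np.any(t == c) else None
            for c in range(len(cm.class_names))]
        report["macro_auc"] = round(macro_auc(class_scores, t), 4)
    return report
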