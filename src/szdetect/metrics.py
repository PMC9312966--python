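"""Confusion-matrix performance metrics and the ROC area.

All ratio metrics use the 0/0 -> 0 convention so they stay defined on
degenerate confusion matrices (e.g. a fold or test set with one class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts; their sum is the evaluated set size."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}")

    @property
    def size(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, the four rates, MCC, and optionally the ROC area."""

    ca: float
    tpr: float
    tnr: float
    fpr: float
    ppv: float
    npv: float
    mcc: float
    auc: float | None = None


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def mcc_score(cm: ConfusionMatrix) -> float:
    """Matthews correlation; 0 if any marginal of the matrix is empty."""
    tp, tn, fp, fn = (float(v) for v in (cm.tp, cm.tn, cm.fp, cm.fn))
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(den)


def metrics(cm: ConfusionMatrix, auc_value: float | None = None) -> MetricSet:
    """The standard metric suite from a confusion matrix."""
    if cm.size == 0:
        raise ValueError("empty confusion matrix")
    return MetricSet(
        ca=_ratio(cm.tp + cm.tn, cm.size),
        tpr=_ratio(cm.tp, cm.tp + cm.fn),
        tnr=_ratio(cm.tn, cm.tn + cm.fp),
        fpr=_ratio(cm.fp, cm.fp + cm.tn),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        mcc=mcc_score(cm),
        auc=auc_value,
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (tie-corrected Mann-Whitney form).

    Equals the trapezoidal area of TPR vs FPR over all score thresholds.
    ``labels`` may be booleans or "Y"/"N" strings.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        pos = labels == "Y"
    else:
        pos = labels.astype(bool)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
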