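"""Selection-performance scoring for variable-selection experiments.

Confusion counts are tallied element-wise between a binary selection
matrix and the binary truth.  The Matthews correlation coefficient is
computed in its normalized form

    MCC = (TP/N - S * P) / sqrt(P S (1 - S)(1 - P)),

with N the total number of indicators, P = (TP + FP)/N the selected
fraction and S = (TP + FN)/N the positive fraction; this is
algebraically identical to the classic four-product formula wherever
both are defined, and is set to 0 by convention when P or S is 0 or 1
(degenerate denominator).  ROC curves sweep the PPI threshold, handling
ties by simultaneous inclusion, with trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ConfusionCounts", "confusion", "acc", "fpr", "fnr", "mcc", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(selected: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Element-wise confusion tally of a selection against the truth."""
    selected = np.asarray(selected).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if selected.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: selected {selected.shape} vs truth {truth.shape}"
        )
    return ConfusionCounts(
        tp=int(np.sum(selected & truth)),
        fp=int(np.sum(selected & ~truth)),
        tn=int(np.sum(~selected & ~truth)),
        fn=int(np.sum(~selected & truth)),
    )


def acc(counts: ConfusionCounts) -> float:
    """Accuracy (TP + TN) / N."""
    return (counts.tp + counts.tn) / counts.n_total


def fpr(counts: ConfusionCounts) -> float:
    """False positive rate FP / (FP + TN); 0 when there are no negatives."""
    denom = counts.fp + counts.tn
    return counts.fp / denom if denom else 0.0


def fnr(counts: ConfusionCounts) -> float:
    """False negative rate FN / (FN + TP); 0 when there are no positives."""
    denom = counts.fn + counts.tp
    return counts.fn / denom if denom else 0.0


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient, normalized form.

    Returns 0.0 when the selected or the positive fraction is 0 or 1,
    where the denominator degenerates.
    """
    N = counts.n_total
    P = (counts.tp + counts.fp) / N
    S = (counts.tp + counts.fn) / N
    if P in (0.0, 1.0) or S in (0.0, 1.0):
        return 0.0
    return (counts.tp / N - S * P) / np.sqrt(P * S * (1.0 - S) * (1.0 - P))


def roc_auc(
    ppi: np.ndarray, truth: np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve and trapezoidal AUC of a score matrix against the truth.

    Thresholds sweep the sorted unique scores; tied scores enter the
    selection simultaneously.  Raises when the truth contains a single
    class, where the ROC is undefined.
    """
    ppi = np.asarray(ppi, dtype=np.float64).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if ppi.shape != truth.shape:
        raise ValueError("ppi and truth must have the same shape")
    if truth.all() or not truth.any():
        raise ValueError("ROC is undefined when the truth has a single class")
    fpr_pts, tpr_pts, _ = _sk_roc_curve(truth.astype(int), ppi)
    auc = float(np.trapezoid(tpr_pts, fpr_pts))
    return (fpr_pts, tpr_pts), auc
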