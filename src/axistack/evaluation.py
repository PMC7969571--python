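"""Agreement and diagnostic statistics.

Implements the overlap and agreement measures used to appraise the pipeline:
the Dice coefficient 2·TP/(2·TP+FP+FN) per class, accuracy / sensitivity /
specificity / Cohen's kappa from binary confusion counts, ROC analysis with
the Youden-optimal cut-off, Pearson correlation, and Wilson score intervals
for binomial proportions.

Also provides the inverse problem: given a cohort size and *printed* (i.e.
rounded) sensitivity / specificity / accuracy percentages, exhaustively
enumerate every integer confusion matrix consistent with them.  This makes
published worked-example statistics (such as kappa values reported alongside
rounded percentages) reproducible without the underlying data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sp_stats
from sklearn import metrics as sk_metrics
from statsmodels.stats.proportion import proportion_confint

from .imaging_io import LabelClass


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts. TN is unused by the Dice coefficient."""

    TP: int
    FP: int
    FN: int
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class BinaryDiagnostics:
    """Diagnostic statistics; an undefined statistic is None, never NaN."""

    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    kappa: Optional[float]
    n: int


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap 2·TP/(2·TP+FP+FN); two empty masks agree vacuously (1.0)."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    true_mask = np.asarray(true_mask, dtype=bool)
    if pred_mask.shape != true_mask.shape:
        raise ValueError("masks must have the same shape")
    tp = int(np.count_nonzero(pred_mask & true_mask))
    fp = int(np.count_nonzero(pred_mask & ~true_mask))
    fn = int(np.count_nonzero(~pred_mask & true_mask))
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def per_class_dice(pred_labels: np.ndarray, true_labels: np.ndarray,
                   classes: Optional[Sequence[int]] = None) -> Dict[int, float]:
    """Dice of the binary mask of each class; by default every class present
    in either map is scored."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("label maps must have the same shape")
    if classes is None:
        classes = sorted(set(np.unique(pred_labels)) | set(np.unique(true_labels)))
    return {int(c): dice(pred_labels == c, true_labels == c) for c in classes}


def mean_foreground_dice(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Mean Dice over the foreground classes present in the reference."""
    classes = [int(c) for c in np.unique(true_labels) if c != LabelClass.background]
    if not classes:
        raise ValueError("reference contains no foreground")
    scores = per_class_dice(pred_labels, true_labels, classes)
    return float(np.mean(list(scores.values())))


def cohen_kappa(counts: ConfusionCounts) -> Optional[float]:
    """(p_o − p_e)/(1 − p_e); None when chance agreement p_e = 1."""
    n = counts.n
    p_o = (counts.TP + counts.TN) / n
    p_e = (
        (counts.TP + counts.FN) * (counts.TP + counts.FP)
        + (counts.TN + counts.FP) * (counts.TN + counts.FN)
    ) / n**2
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def binary_diagnostics(counts: ConfusionCounts) -> BinaryDiagnostics:
    """Accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP), and kappa."""
    n = counts.n
    if n < 1:
        raise ValueError("need at least one observation")
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    return BinaryDiagnostics(
        accuracy=(counts.TP + counts.TN) / n,
        sensitivity=counts.TP / pos if pos >= 1 else None,
        specificity=counts.TN / neg if neg >= 1 else None,
        kappa=cohen_kappa(counts),
        n=n,
    )


# ---------------------------------------------------------------------------
# confusion-matrix reconstruction from printed statistics
# ---------------------------------------------------------------------------

def _printed_decimals(value: float) -> int:
    """Precision at which a percentage was printed: integers ('80') carry 0
    decimals, anything else ('84.3') one decimal."""
    return 0 if float(value) == round(float(value)) else 1


def _rounds_to(raw_pct: np.ndarray, printed: float, decimals: int) -> np.ndarray:
    """Half-up rounding match at the printed precision."""
    scale = 10.0**decimals
    rounded = np.floor(raw_pct * scale + 0.5 + 1e-9) / scale
    return np.abs(rounded - printed) < 1e-9


def reconstruct_confusion(n: int, sensitivity_pct: float, specificity_pct: float,
                          accuracy_pct: float) -> list[ConfusionCounts]:
    """All integer confusion matrices of total n whose sensitivity,
    specificity and accuracy each round (half-up, at the precision printed)
    to the given percentages.  Returns an empty list when none exist."""
    if n < 1:
        raise ValueError("n must be >= 1")
    d_sens = _printed_decimals(sensitivity_pct)
    d_spec = _printed_decimals(specificity_pct)
    d_acc = _printed_decimals(accuracy_pct)

    solutions = []
    for pos in range(1, n):  # both classes must be represented
        neg = n - pos
        tp_all = np.arange(pos + 1)
        tp_ok = tp_all[_rounds_to(100.0 * tp_all / pos, sensitivity_pct, d_sens)]
        if not len(tp_ok):
            continue
        tn_all = np.arange(neg + 1)
        tn_ok = tn_all[_rounds_to(100.0 * tn_all / neg, specificity_pct, d_spec)]
        if not len(tn_ok):
            continue
        total = tp_ok[:, None] + tn_ok[None, :]
        acc_ok = _rounds_to(100.0 * total / n, accuracy_pct, d_acc)
        for i, j in zip(*np.nonzero(acc_ok)):
            tp, tn = int(tp_ok[i]), int(tn_ok[j])
            solutions.append(ConfusionCounts(TP=tp, FN=pos - tp, FP=neg - tn, TN=tn))
    return solutions


# ---------------------------------------------------------------------------
# intervals, correlation, ROC
# ---------------------------------------------------------------------------

def wilson_interval(successes: int, trials: int, confidence: float = 0.95):
    """Wilson score interval for a binomial proportion, as fractions."""
    if not 0 <= successes <= trials or trials < 1:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    lower, upper = proportion_confint(successes, trials, alpha=1.0 - confidence,
                                      method="wilson")
    if successes == trials:
        upper = 1.0
    if successes == 0:
        lower = 0.0
    return float(lower), float(upper)


def pearson(x: Sequence[float], y: Sequence[float]):
    """Pearson product-moment correlation; returns (r, r²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1D arrays with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r = float(sp_stats.pearsonr(x, y).statistic)
    return r, r * r


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_threshold: float
    counts_at_cutoff: ConfusionCounts
    diagnostics_at_cutoff: BinaryDiagnostics


def roc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve with trapezoidal AUC and the Youden-optimal cut-off.

    The cut-off maximizes J = sensitivity + specificity − 1; ties are broken
    toward the lower threshold.  Accuracy and kappa at the cut-off are
    reported via :func:`binary_diagnostics` with the convention that a score
    >= threshold calls the case positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = sk_metrics.roc_curve(labels, scores)
    auc = float(sk_metrics.auc(fpr, tpr))
    j = tpr - fpr
    # thresholds are descending; the last index among maxima is the lowest
    best = int(np.flatnonzero(j == j.max())[-1])
    cutoff = float(thresholds[best])
    pred = scores >= cutoff
    counts = ConfusionCounts(
        TP=int(np.count_nonzero(pred & (labels == 1))),
        FP=int(np.count_nonzero(pred & (labels == 0))),
        FN=int(np.count_nonzero(~pred & (labels == 1))),
        TN=int(np.count_nonzero(~pred & (labels == 0))),
    )
    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
        youden_threshold=cutoff, counts_at_cutoff=counts,
        diagnostics_at_cutoff=binary_diagnostics(counts),
    )
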