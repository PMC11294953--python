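"""Classification metrics, ROC/AUC and the DeLong variance of the AUC.

The AUC is computed through the rank (Mann–Whitney) formulation with the
mid-rank tie convention; its standard error follows DeLong's placement-value
estimator, and the confidence interval is a normal approximation on the AUC
scale truncated to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray  # 1 - specificity
    tpr: np.ndarray  # sensitivity
    auc: float
    auc_se: float | None = None
    ci: tuple | None = None
    level: float = 0.95


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float


def _check_scores(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC with ties counting 1/2."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and rank-based AUC (positive class = mutated = 1)."""
    scores, labels = _check_scores(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr,
                     auc=_rank_auc(scores, labels))


def delong_placements(scores, labels):
    """DeLong structural components (V10 per positive, V01 per negative)."""
    scores, labels = _check_scores(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # mid-rank convention: ties contribute 1/2
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


def delong_ci(scores, labels, level: float = 0.95) -> ROCResult:
    """AUC with DeLong standard error and normal-approximation CI."""
    scores, labels = _check_scores(scores, labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if min(n0, n1) < 2:
        raise ValueError("DeLong variance needs at least 2 samples per class")
    v10, v01 = delong_placements(scores, labels)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        warnings.warn("zero DeLong variance (perfect or degenerate "
                      "separation); CI collapses to a point", stacklevel=2)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
                     auc_se=se, ci=(lo, hi), level=level)


def class_metrics(predictions, labels) -> ClassMetrics:
    """Confusion-count metrics; undefined ratios are NaN with a warning."""
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    tp = int(((predictions == 1) & (labels == 1)).sum())
    fp = int(((predictions == 1) & (labels == 0)).sum())
    tn = int(((predictions == 0) & (labels == 0)).sum())
    fn = int(((predictions == 0) & (labels == 1)).sum())

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported "
                          "as NaN", stacklevel=3)
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        f1 = float("nan") if (np.isnan(prec) or np.isnan(sens)) else 0.0
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return ClassMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / predictions.size,
        sensitivity=sens, specificity=spec, precision=prec, f1=f1,
    )
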