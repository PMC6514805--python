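"""Binary-classification metrics, empirical ROC/AUC, and paired AUC comparison.

Sensitivity, specificity, accuracy and the Matthews correlation coefficient
are computed from the confusion matrix; the AUC is the empirical
(Mann-Whitney) area with half-credit for ties; two correlated AUCs measured on
the same test samples are compared with DeLong's nonparametric two-tailed
test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/TN/FP/FN from 0/1 truth and prediction vectors."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between truth and predictions")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass
class MetricSet:
    sn: float
    sp: float
    acc: float
    mcc: float | None  # None when the MCC denominator vanishes
    auc: float | None = None


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity, accuracy and MCC from a confusion matrix.

    ``SN = TP/(TP+FN)``, ``SP = TN/(TN+FP)``, ``ACC = (TP+TN)/total``,
    ``MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))``.
    A vanishing MCC denominator is reported as undefined (None) with a
    warning, never silently coerced to zero.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    sn = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / cm.total
    denom = math.sqrt((tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    if denom == 0:
        warnings.warn("MCC undefined: a confusion-matrix margin is zero", stacklevel=2)
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / denom
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _check_scores(y, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")
    return y, scores


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def roc_auc(y, scores) -> ROCResult:
    """Empirical ROC curve and AUC (Mann-Whitney, half-credit for ties)."""
    y, scores = _check_scores(y, scores)
    fpr, tpr, thr = roc_curve(y, scores)
    m = int(y.sum())
    n = len(y) - m
    ranks = _midrank(scores)
    auc = (ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n)
    return ROCResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thr)


@dataclass(frozen=True)
class AUCComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float


def _delong_components(y: np.ndarray, scores: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong structural components V10 (per positive) and V01
    (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def compare_auc(y, scores_a, scores_b) -> AUCComparison:
    """DeLong's two-tailed test for two correlated AUCs on the same samples.

    Returns the two AUCs, their difference, the z statistic, and the two-sided
    p-value from the normal approximation.  Identical score vectors give
    p = 1.0; the p-value is symmetric in the two methods.
    """
    y, scores_a = _check_scores(y, scores_a)
    _, scores_b = _check_scores(y, scores_b)
    if len(scores_a) != len(scores_b):
        raise ValueError("the two methods must score the same samples")

    auc_a, v10_a, v01_a = _delong_components(y, scores_a)
    auc_b, v10_b, v01_b = _delong_components(y, scores_b)
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0 if delta == 0 else math.copysign(math.inf, delta)
    else:
        z = delta / math.sqrt(var)
    p = float(2.0 * norm.sf(abs(z))) if math.isfinite(z) else 0.0
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)  # keep p in (0, 1]
    return AUCComparison(auc_a=auc_a, auc_b=auc_b, delta=delta, z=z, p_value=p)
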