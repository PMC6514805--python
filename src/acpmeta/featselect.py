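"""Two-step feature selection: F-score ranking + sequential forward search.

Step 1 ranks every feature by its F-score (between-class over within-class
scatter).  Step 2 walks the ranked list, adding features one at a time and
scoring each prefix by mean stratified k-fold cross-validated accuracy of an
RBF-SVM; the shortest prefix attaining the maximum accuracy is the optimal
feature set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .encoders import FeatureMatrix
from .svm_models import CVConfig, SVMParams, make_pipeline

# Features that perfectly separate the classes have zero pooled within-class
# variance; they are ranked ahead of everything else with this finite stand-in
# so downstream sorting stays well defined.
_SEPARABLE_FSCORE = 1e300


@dataclass
class RankedFeatures:
    """F-scores and the descending-score ordering of a feature matrix."""

    feature_names: list[str]
    fscores: np.ndarray
    order: np.ndarray  # permutation: order[0] is the top-ranked column index

    def ranked_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.order]


@dataclass
class OptimalFeatureSet:
    """The accuracy-maximizing ranked prefix found by the forward search."""

    scheme: str
    selected: list[str]
    selected_idx: np.ndarray
    cv_accuracy: float
    search_trace: list[tuple[int, float, float]] = field(default_factory=list)
    # trace rows: (prefix_length, mean_accuracy, sd_accuracy)

    def write_trace(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["prefix_length", "mean_accuracy", "sd"])
            for row in self.search_trace:
                w.writerow(row)

    def write_features(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.selected) + "\n")


def _as_xy(X: FeatureMatrix | np.ndarray, y=None):
    if isinstance(X, FeatureMatrix):
        names = X.feature_names
        values = X.values
        if y is None:
            y = X.labels
    else:
        values = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(values.shape[1])]
    if y is None:
        raise ValueError("labels are required")
    y = np.asarray(y)
    return values, np.asarray(y), names


def f_score_rank(X: FeatureMatrix | np.ndarray, y=None) -> RankedFeatures:
    """Rank features by F-score.

    For feature i with positive/negative sample values ``x+``/``x-``::

        F(i) = [(mean(x+) - mean(x))^2 + (mean(x-) - mean(x))^2]
               / [var1(x+) + var1(x-)]

    where ``var1`` is the one-degree-of-freedom-corrected sum of squared
    deviations and ``mean(x)`` the grand mean.  Constant features (zero
    numerator and denominator) get F = 0; perfectly separating features (zero
    denominator, positive numerator) are ranked first.  Ties keep original
    column order.
    """
    values, y, names = _as_xy(X, y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"binary labels required, got classes {classes}")
    pos = values[y == classes.max()]
    neg = values[y == classes.min()]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 samples per class")

    grand = values.mean(axis=0)
    num = (pos.mean(axis=0) - grand) ** 2 + (neg.mean(axis=0) - grand) ** 2
    denom = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / denom
    f = np.where(denom == 0, np.where(num == 0, 0.0, _SEPARABLE_FSCORE), f)
    # stable mergesort keeps original column order on ties
    order = np.argsort(-f, kind="stable")
    return RankedFeatures(list(names), f, order)


def sequential_forward_search(
    X: FeatureMatrix | np.ndarray,
    y=None,
    ranked: RankedFeatures | None = None,
    cv: CVConfig | None = None,
    svm: SVMParams | None = None,
    step: int = 1,
    max_features: int | None = None,
    scheme: str = "",
) -> OptimalFeatureSet:
    """Prefix-only forward search over the ranked feature list.

    Prefix lengths ``1, 1+step, 1+2*step, ...`` (always including the full
    dimension, capped at ``max_features``) are scored by mean stratified
    k-fold CV accuracy of an RBF-SVM with fixed hyperparameters (default
    C=1, gamma=1/m); the shortest prefix achieving the maximum is returned
    together with the full accuracy trace.
    """
    values, y, names = _as_xy(X, y)
    if ranked is None:
        ranked = f_score_rank(values, y)
    if list(ranked.feature_names) != list(names):
        raise ValueError("ranking is inconsistent with the matrix columns")
    cv = cv or CVConfig()
    svm = svm or SVMParams(C=1.0, gamma="auto")

    _, counts = np.unique(y, return_counts=True)
    if cv.k > counts.min():
        raise ValueError(f"{cv.k}-fold CV needs >= {cv.k} samples per class")

    D = values.shape[1]
    cap = min(D, max_features) if max_features else D
    lengths = sorted(set(range(1, cap + 1, step)) | {cap})
    splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)

    trace: list[tuple[int, float, float]] = []
    best_m, best_acc = lengths[0], -1.0
    for m in lengths:
        cols = ranked.order[:m]
        scores = cross_val_score(
            make_pipeline(svm, seed=cv.seed, probability=False),
            values[:, cols],
            y,
            cv=splitter,
            scoring="accuracy",
        )
        acc, sd = float(scores.mean()), float(scores.std())
        trace.append((m, acc, sd))
        if acc > best_acc:  # strict: ties keep the smaller prefix
            best_m, best_acc = m, acc
    idx = ranked.order[:best_m]
    return OptimalFeatureSet(
        scheme=scheme,
        selected=[names[i] for i in idx],
        selected_idx=np.array(idx),
        cv_accuracy=best_acc,
        search_trace=trace,
    )


def reduction_percentage(original_dim: int, optimal_dim: int) -> float:
    """Percent of features removed by selection: 100 * (1 - optimal/original)."""
    if original_dim <= 0 or optimal_dim < 0 or optimal_dim > original_dim:
        raise ValueError("dimensions must satisfy 0 <= optimal <= original, original > 0")
    return 100.0 * (1.0 - optimal_dim / original_dim)
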