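"""Per-encoding RBF-SVM base models: grid search, repeated CV, training.

A base model bundles one encoding scheme, its selected feature subset, a
standardization step and a tuned RBF-SVM with calibrated probability output.
Standardization is always fitted inside the training folds (scikit-learn
pipelines), so no information leaks from held-out data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import __version__
from .encoders import FeatureMatrix, encode_matrix
from .evalmetrics import MetricSet, confusion_from_predictions, metrics, roc_auc
from .seqio import PeptideSet
from .tables import PropertyTables, default_tables


@dataclass(frozen=True)
class SVMParams:
    """RBF-SVM hyperparameters (penalty C, kernel width gamma)."""

    C: float = 1.0
    gamma: float | str = "scale"
    kernel: str = "rbf"


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation layout: k folds, number of repeats, fold seed."""

    k: int = 10
    repeats: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def default_grid() -> dict[str, list[float]]:
    """The canonical tuning grid: C = 2^-5..2^15 (exponent step 2),
    gamma = 2^-15..2^15 (exponent step 1)."""
    return {
        "C": [2.0**e for e in range(-5, 16, 2)],
        "gamma": [2.0**e for e in range(-15, 16)],
    }


def small_grid() -> dict[str, list[float]]:
    """A coarse 4x4 sub-grid of the canonical one, for desk-scale runs."""
    return {
        "C": [2.0**e for e in (-3, 0, 3, 7)],
        "gamma": [2.0**e for e in (-7, -3, 0, 3)],
    }


def make_pipeline(
    params: SVMParams,
    seed: int = 0,
    probability: bool = True,
    calibration_folds: int = 5,
) -> Pipeline:
    """Standardizer + RBF-SVM pipeline.

    With ``probability=True`` the SVM decision values are mapped to
    probabilities by Platt sigmoid calibration fitted on an internal
    (unshuffled, hence deterministic) k-fold split of the training data.
    ``seed`` is kept for API symmetry; no step here is stochastic.
    """
    svc = SVC(kernel=params.kernel, C=params.C, gamma=params.gamma)
    est = (
        CalibratedClassifierCV(svc, method="sigmoid", cv=calibration_folds, ensemble=False)
        if probability
        else svc
    )
    return Pipeline([("scale", StandardScaler()), ("svm", est)])


def _splitter(cv: CVConfig, repeat: int = 0) -> StratifiedKFold:
    return StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed + repeat)


def _check_labels(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"binary labels required, got classes {classes}")
    if counts.min() < k:
        raise ValueError(f"{k}-fold CV needs >= {k} samples in each class")


def grid_search(
    X: FeatureMatrix | np.ndarray,
    y,
    grid: dict[str, Iterable[float]] | None = None,
    cv: CVConfig | None = None,
) -> SVMParams:
    """Exhaustive (C, gamma) search maximizing mean k-fold CV accuracy.

    Candidates are evaluated on identical folds; ties are broken toward the
    smaller C, then the smaller gamma, so the result does not depend on the
    enumeration order of the supplied grid.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = cv or CVConfig()
    _check_labels(y, cv.k)
    grid = grid or default_grid()
    pairs = sorted((float(c), float(g)) for c in grid["C"] for g in grid["gamma"])
    if not pairs:
        raise ValueError("empty grid")

    splitter = _splitter(cv)
    best: tuple[float, float] | None = None
    best_acc = -1.0
    for c, g in pairs:
        params = SVMParams(C=c, gamma=g)
        acc = cross_val_score(
            make_pipeline(params, seed=cv.seed, probability=False),
            values,
            y,
            cv=splitter,
            scoring="accuracy",
        ).mean()
        if acc > best_acc:  # strict: first (smallest C, gamma) wins ties
            best, best_acc = (c, g), acc
    assert best is not None
    return SVMParams(C=best[0], gamma=best[1])


@dataclass
class CVReport:
    """Pooled held-out metrics per repeat, plus their mean and SD."""

    per_repeat: list[MetricSet]
    mean: dict[str, float]
    sd: dict[str, float]


def _aggregate(reports: list[MetricSet]) -> tuple[dict[str, float], dict[str, float]]:
    keys = ("sn", "sp", "acc", "mcc", "auc")
    mean, sd = {}, {}
    for k in keys:
        vals = [getattr(r, k) for r in reports if getattr(r, k) is not None]
        mean[k] = float(np.mean(vals)) if vals else float("nan")
        sd[k] = float(np.std(vals)) if vals else float("nan")
    return mean, sd


def repeated_cv(
    X: FeatureMatrix | np.ndarray,
    y,
    params: SVMParams,
    cv: CVConfig | None = None,
) -> CVReport:
    """Repeated stratified k-fold CV with pooled held-out predictions.

    Each repeat re-partitions the data (fold seed = cv.seed + repeat index),
    collects every sample's held-out predicted probability, and computes
    SN/SP/ACC/MCC at the 0.5 threshold plus the ROC AUC.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = cv or CVConfig()
    _check_labels(y, cv.k)

    reports: list[MetricSet] = []
    for r in range(cv.repeats):
        proba = cross_val_predict(
            make_pipeline(params, seed=cv.seed + r),
            values,
            y,
            cv=_splitter(cv, r),
            method="predict_proba",
        )[:, 1]
        yhat = (proba >= 0.5).astype(int)
        ms = metrics(confusion_from_predictions(y, yhat))
        ms.auc = roc_auc(y, proba).auc
        reports.append(ms)
    mean, sd = _aggregate(reports)
    return CVReport(reports, mean, sd)


class BaseModel:
    """One encoding's scaler + selected features + tuned probabilistic RBF-SVM."""

    def __init__(
        self,
        scheme: str,
        selected_features: list[str],
        selected_idx: np.ndarray,
        params: SVMParams,
        seed: int = 0,
        tables: PropertyTables | None = None,
        search_accuracy: float | None = None,
    ) -> None:
        self.scheme = scheme
        self.selected_features = list(selected_features)
        self.selected_idx = np.asarray(selected_idx, dtype=int)
        self.params = params
        self.seed = seed
        self.tables = tables or default_tables()
        self.search_accuracy = search_accuracy
        self.pipeline: Pipeline = make_pipeline(params, seed=seed, probability=True)
        self.fitted_ = False

    # --- feature plumbing -------------------------------------------------

    def encode(self, pset: PeptideSet) -> np.ndarray:
        """Encode peptides and restrict to the selected columns, in order."""
        fm = encode_matrix(pset, self.scheme, self.tables)
        return fm.values[:, self.selected_idx]

    # --- fitting / prediction ---------------------------------------------

    def fit_values(self, X: np.ndarray, y) -> "BaseModel":
        self.pipeline.fit(X, np.asarray(y))
        self.fitted_ = True
        return self

    def fit(self, pset: PeptideSet, y) -> "BaseModel":
        return self.fit_values(self.encode(pset), y)

    def fresh_pipeline(self) -> Pipeline:
        """Unfitted clone with identical hyperparameters (for stacking folds)."""
        return clone(self.pipeline)

    def predict_proba(self, pset: PeptideSet) -> np.ndarray:
        """Calibrated positive-class probability per peptide, in [0, 1]."""
        if not self.fitted_:
            raise RuntimeError("base model is not fitted")
        return self.pipeline.predict_proba(self.encode(pset))[:, 1]

    # --- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "scheme": self.scheme,
            "selected_features": self.selected_features,
            "selected_idx": self.selected_idx.tolist(),
            "params": asdict(self.params),
            "seed": self.seed,
            "search_accuracy": self.search_accuracy,
            "tables_checksum": self.tables.checksum(),
            "package_version": __version__,
        }
        (d / "base_model.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self.pipeline, d / "pipeline.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "BaseModel":
        d = Path(directory)
        meta = json.loads((d / "base_model.json").read_text())
        tables = default_tables()
        if meta["tables_checksum"] != tables.checksum():
            raise ValueError("property tables differ from the ones the model was trained with")
        model = cls(
            scheme=meta["scheme"],
            selected_features=meta["selected_features"],
            selected_idx=np.array(meta["selected_idx"]),
            params=SVMParams(**meta["params"]),
            seed=meta["seed"],
            tables=tables,
            search_accuracy=meta["search_accuracy"],
        )
        model.pipeline = joblib.load(d / "pipeline.joblib")
        model.fitted_ = True
        return model


def train_base_model(
    pset: PeptideSet,
    y,
    scheme: str,
    cv: CVConfig | None = None,
    grid: dict[str, list[float]] | None = None,
    tables: PropertyTables | None = None,
    select: bool = True,
    sfs_step: int = 1,
    sfs_max: int | None = None,
    tune: bool = True,
) -> BaseModel:
    """Full base-model protocol for one encoding.

    encode -> F-score ranking -> sequential forward search (fixed default SVM)
    -> grid search on the optimal subset -> final probabilistic fit.  ``select``
    and ``tune`` switch the selection and grid-search stages off (the full
    feature set / default hyperparameters are then used), and ``sfs_step`` /
    ``sfs_max`` coarsen the prefix search for large encodings.
    """
    from .featselect import f_score_rank, sequential_forward_search  # local: avoids cycle

    tables = tables or default_tables()
    cv = cv or CVConfig()
    y = np.asarray(y)
    fm = encode_matrix(pset, scheme, tables)

    if select:
        try:
            ranked = f_score_rank(fm, y)
            opt = sequential_forward_search(
                fm, y, ranked, cv=cv, step=sfs_step, max_features=sfs_max, scheme=scheme
            )
        except ValueError as exc:
            raise ValueError(f"feature selection failed for {scheme}: {exc}") from exc
        selected, idx, search_acc = opt.selected, opt.selected_idx, opt.cv_accuracy
    else:
        selected = list(fm.feature_names)
        idx = np.arange(len(selected))
        search_acc = None

    X_sel = fm.values[:, idx]
    if tune:
        try:
            params = grid_search(X_sel, y, grid=grid, cv=cv)
        except ValueError as exc:
            raise ValueError(f"grid search failed for {scheme}: {exc}") from exc
    else:
        params = SVMParams()

    model = BaseModel(
        scheme, selected, idx, params, seed=cv.seed, tables=tables, search_accuracy=search_acc
    )
    return model.fit_values(X_sel, y)
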