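"""Stacked meta-predictor: an RBF-SVM over the seven base-model probabilities.

Each of the seven encoding-specific base models emits a calibrated probability
that a peptide is an anticancer peptide; those seven probabilities, in a fixed
canonical order, are the only inputs of the second-level SVM.  Meta-training
features are produced out-of-fold by default (each training peptide is scored
by base models that never saw it), the standard guard against stacking
leakage; an in-fold variant is available for comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import __version__
from .encoders import CANONICAL_SCHEMES, FeatureMatrix, encode_matrix
from .seqio import PeptideSet
from .svm_models import (
    BaseModel,
    CVConfig,
    SVMParams,
    grid_search,
    make_pipeline,
    small_grid,
)

META_FEATURE_NAMES = tuple(f"prob.{s}" for s in CANONICAL_SCHEMES)


def _ordered_bases(bases: list[BaseModel] | dict[str, BaseModel]) -> list[BaseModel]:
    if isinstance(bases, dict):
        by_scheme = dict(bases)
    else:
        by_scheme = {}
        for b in bases:
            if b.scheme in by_scheme:
                raise ValueError(f"duplicate base model for scheme {b.scheme}")
            by_scheme[b.scheme] = b
    missing = [s for s in CANONICAL_SCHEMES if s not in by_scheme]
    if missing:
        raise ValueError(f"missing base models for schemes: {missing}")
    if len(by_scheme) != len(CANONICAL_SCHEMES):
        extra = sorted(set(by_scheme) - set(CANONICAL_SCHEMES))
        raise ValueError(f"unexpected base-model schemes: {extra}")
    return [by_scheme[s] for s in CANONICAL_SCHEMES]


def build_meta_features(
    bases: list[BaseModel] | dict[str, BaseModel], pset: PeptideSet
) -> FeatureMatrix:
    """n x 7 matrix of base-model probabilities in canonical scheme order."""
    ordered = _ordered_bases(bases)
    cols = [b.predict_proba(pset) for b in ordered]
    return FeatureMatrix(pset.ids(), list(META_FEATURE_NAMES), np.column_stack(cols))


def _oof_meta_features(
    ordered: list[BaseModel], pset: PeptideSet, y: np.ndarray, cv: CVConfig
) -> np.ndarray:
    """Out-of-fold base probabilities: per fold, refit a clone of every base
    pipeline (fixed features and hyperparameters) on the fold-training rows and
    score the held-out rows."""
    n = len(pset)
    k = min(cv.k, int(np.bincount(y).min()))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=cv.seed)
    feats = np.zeros((n, len(ordered)))
    encoded = [b.encode(pset) for b in ordered]
    for train, test in splitter.split(np.zeros(n), y):
        for j, base in enumerate(ordered):
            pipe = base.fresh_pipeline()
            pipe.fit(encoded[j][train], y[train])
            feats[test, j] = pipe.predict_proba(encoded[j][test])[:, 1]
    return feats


class MetaPredictor:
    """Seven fitted base models plus the stacked probability-space SVM."""

    def __init__(
        self,
        bases: list[BaseModel] | dict[str, BaseModel],
        meta_params: SVMParams,
        seed: int = 0,
        threshold: float = 0.5,
    ) -> None:
        self.bases = _ordered_bases(bases)
        self.meta_params = meta_params
        self.seed = seed
        self.threshold = threshold
        self.pipeline = make_pipeline(meta_params, seed=seed, probability=True)
        self.fitted_ = False

    def predict_proba(self, pset: PeptideSet) -> np.ndarray:
        if not self.fitted_:
            raise RuntimeError("meta predictor is not fitted")
        feats = build_meta_features(self.bases, pset)
        return self.pipeline.predict_proba(feats.values)[:, 1]

    def predict(self, pset: PeptideSet) -> pd.DataFrame:
        """Per-peptide probability and label, plus the 7 base probabilities.

        A peptide at exactly the threshold is labelled positive (>= rule).
        """
        feats = build_meta_features(self.bases, pset)
        proba = self.pipeline.predict_proba(feats.values)[:, 1]
        df = pd.DataFrame(
            {
                "id": pset.ids(),
                "probability": proba,
                "label": np.where(proba >= self.threshold, "ACP", "non-ACP"),
            }
        )
        for j, name in enumerate(META_FEATURE_NAMES):
            df[name] = feats.values[:, j]
        return df

    # --- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "meta_params": asdict(self.meta_params),
            "seed": self.seed,
            "threshold": self.threshold,
            "schemes": list(CANONICAL_SCHEMES),
            "package_version": __version__,
        }
        (d / "meta_model.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self.pipeline, d / "meta_pipeline.joblib")
        for base in self.bases:
            base.save(d / f"base_{base.scheme}")

    @classmethod
    def load(cls, directory: str | Path) -> "MetaPredictor":
        d = Path(directory)
        meta = json.loads((d / "meta_model.json").read_text())
        bases = [BaseModel.load(d / f"base_{s}") for s in meta["schemes"]]
        model = cls(
            bases,
            SVMParams(**meta["meta_params"]),
            seed=meta["seed"],
            threshold=meta["threshold"],
        )
        model.pipeline = joblib.load(d / "meta_pipeline.joblib")
        model.fitted_ = True
        return model


def train_meta(
    bases: list[BaseModel] | dict[str, BaseModel],
    pset: PeptideSet,
    y,
    cv: CVConfig | None = None,
    grid: dict[str, list[float]] | None = None,
    out_of_fold: bool = True,
    tune: bool = True,
    threshold: float = 0.5,
) -> MetaPredictor:
    """Train the stacked SVM over the 7-column probability feature space.

    With ``out_of_fold=True`` (default) meta-training features come from base
    pipelines refitted per CV fold, so no training peptide is scored by a model
    that saw it.  ``tune=False`` keeps default meta hyperparameters;
    otherwise a grid search (default: the coarse grid) picks (C, gamma).
    """
    cv = cv or CVConfig()
    y = np.asarray(y)
    ordered = _ordered_bases(bases)

    if out_of_fold:
        feats = _oof_meta_features(ordered, pset, y, cv)
    else:
        feats = build_meta_features(ordered, pset).values

    if tune:
        params = grid_search(feats, y, grid=grid or small_grid(), cv=cv)
    else:
        params = SVMParams()

    model = MetaPredictor(ordered, params, seed=cv.seed, threshold=threshold)
    model.pipeline.fit(feats, y)
    model.fitted_ = True
    return model


def train_full_stack(
    pset: PeptideSet,
    y,
    cv: CVConfig | None = None,
    grid: dict[str, list[float]] | None = None,
    tables=None,
    select: bool = True,
    sfs_step: int = 1,
    sfs_max: int | None = None,
    tune: bool = True,
    out_of_fold: bool = True,
) -> MetaPredictor:
    """End-to-end training: seven base models, then the stacked meta-SVM."""
    from .svm_models import train_base_model

    cv = cv or CVConfig()
    bases = [
        train_base_model(
            pset,
            y,
            scheme,
            cv=cv,
            grid=grid,
            tables=tables,
            select=select,
            sfs_step=sfs_step,
            sfs_max=sfs_max,
            tune=tune,
        )
        for scheme in CANONICAL_SCHEMES
    ]
    return train_meta(bases, pset, y, cv=cv, grid=grid, out_of_fold=out_of_fold, tune=tune)
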