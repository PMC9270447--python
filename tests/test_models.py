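"""Regressor contract: tuning, fitting, scoring, importance, quality gate."""

import numpy as np
import pytest

from agebench import (
    HyperparamSet,
    ModelFamily,
    baseline_quality,
    compute_importance,
    fit_regressor,
    score_mse,
    tune_hyperparameters,
)
from agebench.models import FeatureSchemaError, UndefinedR2Error, _subset
from agebench import ScenarioConfig, generate_scenario, slice_window, TimeWindow

from conftest import make_dataset


def _linear_ds(n=200, noise=0.0, seed=0, coef=(2.0, 0.0)):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(coef)))
    y = X @ np.asarray(coef) + noise * rng.standard_normal(n)
    ds = make_dataset(np.linspace(0, 100, n), target=y, n_features=len(coef), seed=seed)
    ds.features = X
    return ds


def _analytic_ridge(ds, alpha):
    """Closed-form ridge on standardized features (independent oracle)."""
    Z = (ds.features - ds.features.mean(0)) / ds.features.std(0)
    p = Z.shape[1]
    return np.linalg.solve(Z.T @ Z + alpha * np.eye(p), Z.T @ ds.target)


class TestTuning:
    def test_single_grid_point_returned(self):
        ds = _linear_ds(noise=0.5)
        hps = tune_hyperparameters(ModelFamily("RV", {"alpha": [3.0]}), ds)
        assert hps.values == {"alpha": 3.0}
        assert np.isfinite(hps.cv_score)

    def test_small_penalty_wins_on_noiseless_linear_data(self):
        ds = _linear_ds(noise=0.0)
        hps = tune_hyperparameters(ModelFamily("RV", {"alpha": [0.01, 100.0]}), ds)
        assert hps.values["alpha"] == 0.01
        # oracle: closed-form ridge validation MSE ordering on a chronological split
        train, val = _subset(ds, np.arange(150)), _subset(ds, np.arange(150, 200))
        mses = {}
        for alpha in (0.01, 100.0):
            beta = _analytic_ridge(train, alpha)
            Z = (val.features - train.features.mean(0)) / train.features.std(0)
            mses[alpha] = np.mean((val.target - Z @ beta) ** 2)
        assert mses[0.01] < mses[100.0]

    def test_tie_broken_toward_shallower_trees(self):
        ds = make_dataset(np.linspace(0, 100, 60), target=np.full(60, 4.0))
        hps = tune_hyperparameters(ModelFamily("RF", {"n_estimators": [10], "max_depth": [2, 8]}), ds)
        assert hps.values["max_depth"] == 2  # equal (zero) CV error; simpler model wins


class TestFitPredict:
    @pytest.mark.parametrize("family,atol", [("RV", 1e-8), ("RF", 1e-8), ("XG", 1e-4), ("NN", 0.05)])
    def test_constant_target_predicted_everywhere(self, family, atol):
        ds = make_dataset(np.linspace(0, 50, 80), target=np.full(80, 3.0))
        grid = {"RV": {"alpha": 1.0}, "RF": {"n_estimators": 10}, "XG": {"n_estimators": 10},
                "NN": {"hidden_layer_sizes": [8], "solver": "lbfgs"}}[family]
        model = fit_regressor(family, grid, ds, seed=0)
        np.testing.assert_allclose(model.predict(ds.features), 3.0, atol=atol)

    @pytest.mark.parametrize("family", ["RV", "RF", "XG", "NN"])
    def test_identical_seed_reproduces_predictions(self, family):
        ds = _linear_ds(noise=1.0, n=120)
        kwargs = {"NN": {"hidden_layer_sizes": [8]}}.get(family, {})
        a = fit_regressor(family, kwargs, ds, seed=42).predict(ds.features)
        b = fit_regressor(family, kwargs, ds, seed=42).predict(ds.features)
        np.testing.assert_array_equal(a, b)

    def test_ridge_recovers_dominant_coefficient(self):
        ds = _linear_ds(noise=0.0, coef=(2.0, 0.0))
        model = fit_regressor("RV", {"alpha": 1e-6}, ds)
        # OLS oracle on standardized features
        ols = np.linalg.lstsq(
            (ds.features - ds.features.mean(0)) / ds.features.std(0), ds.target, rcond=None
        )[0]
        np.testing.assert_allclose(model.estimator.coef_, ols, atol=1e-4)
        assert score_mse(model, ds) < 1e-10

    def test_zero_variance_feature_dropped_with_warning(self):
        ds = _linear_ds(noise=0.5)
        ds.features[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_regressor("RV", {"alpha": 1.0}, ds)
        assert model.dropped_features == ["x2"]
        assert model.predict(ds.features).shape == (ds.n_records,)

    def test_scaler_computed_on_train_only(self):
        ds = _linear_ds(noise=1.0, n=300)
        train = _subset(ds, np.arange(200))
        model = fit_regressor("RV", {"alpha": 1.0}, train)
        np.testing.assert_allclose(model.center, train.features.mean(0))
        before = model.center.copy()
        score_mse(model, _subset(ds, np.arange(200, 300)))  # evaluation must not touch the scaler
        np.testing.assert_array_equal(model.center, before)


class TestScore:
    def test_hand_arithmetic(self):
        ds = make_dataset([0.0, 1.0], target=[0.0, 2.0])
        model = fit_regressor("RV", {"alpha": 1.0}, ds)
        model._constant_prediction = 1.0  # force predictions [1, 1]
        assert score_mse(model, ds) == 1.0

    def test_schema_mismatch_names_features(self):
        ds = _linear_ds()
        model = fit_regressor("RV", {"alpha": 1.0}, ds)
        other = make_dataset([0.0, 1.0], n_features=2)
        other.feature_names = ["a", "b"]
        with pytest.raises(FeatureSchemaError, match="missing"):
            score_mse(model, other)


class TestImportance:
    def test_ridge_importance_matches_analytic_solution(self):
        ds = _linear_ds(noise=0.1, coef=(2.0, 0.0), n=400)
        model = fit_regressor("RV", {"alpha": 1.0}, ds)
        vec = compute_importance(model, ds)
        oracle = _analytic_ridge(ds, 1.0)
        np.testing.assert_allclose(vec, oracle / np.linalg.norm(oracle), atol=1e-6)
        assert vec[0] > 0.99 and abs(vec[1]) < 0.1

    def test_unit_norm_when_nonzero(self):
        ds = _linear_ds(noise=0.5, n=200)
        model = fit_regressor("RF", {"n_estimators": 20}, ds)
        vec = compute_importance(model, ds, seed=1)
        assert np.linalg.norm(vec) == pytest.approx(1.0)

    def test_constant_target_gives_zero_vector(self):
        ds = make_dataset(np.linspace(0, 50, 80), target=np.full(80, 3.0))
        model = fit_regressor("RV", {"alpha": 1.0}, ds)
        np.testing.assert_array_equal(compute_importance(model, ds), np.zeros(2))

    def test_irrelevant_feature_near_zero_permutation_importance(self):
        ds = _linear_ds(noise=0.3, coef=(2.0, 0.0), n=500)
        model = fit_regressor("XG", {"n_estimators": 50}, ds)
        vec = compute_importance(model, ds, seed=0, n_shuffles=50)
        assert vec[1] < 0.15  # feature absent from the generating process


class TestQualityGate:
    def test_noiseless_fit_too_good_for_band(self):
        ds = _linear_ds(noise=0.0, n=200)
        q = baseline_quality("RV", {"alpha": 0.01}, ds)
        assert q.r2_cv > 0.95 and not q.passed_gate

    def test_pure_noise_fails_gate(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(np.linspace(0, 100, 300), target=rng.standard_normal(300))
        q = baseline_quality("RV", {"alpha": 1.0}, ds)
        assert q.r2_cv < 0.2 and not q.passed_gate

    def test_default_scenario_calibrated_to_band(self, stationary_ds):
        year = slice_window(stationary_ds, TimeWindow(0.0, 365.0))
        q = baseline_quality("RV", {"alpha": 1.0}, year)
        assert q.passed_gate
        assert q.r2_cv == pytest.approx(0.8, abs=0.05)  # generator's analytic signal fraction

    def test_zero_variance_target_undefined(self):
        ds = make_dataset(np.linspace(0, 100, 100), target=np.full(100, 1.0))
        with pytest.raises(UndefinedR2Error):
            baseline_quality("RV", {"alpha": 1.0}, ds)
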