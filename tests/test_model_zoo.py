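"""Tests for the five analysis models and the tuning protocol."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from predsize.metrics import mape
from predsize.model_zoo import (
    default_grid,
    fit_bagging,
    fit_boosting,
    fit_lr_main,
    fit_lr_spline,
    fit_model,
    fit_random_forest,
    tune_hyperparameters,
)


def logistic_data(rng, n, beta, intercept=-2.0):
    X = pd.DataFrame(rng.standard_normal((n, len(beta))), columns=[f"x{i}" for i in range(len(beta))])
    p = expit(intercept + X.to_numpy() @ np.asarray(beta))
    y = (rng.random(n) < p).astype(int)
    return X, y, p


class TestLogisticMain:
    def test_two_by_two_closed_form(self):
        # counts: exposed (a events, b non-events), unexposed (c, d)
        a, b, c, d = 30, 70, 10, 90
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        model = fit_lr_main(pd.DataFrame({"x": x}), y)
        slope = model.metadata["coef"][0]
        assert slope == pytest.approx(np.log(a * d / (b * c)), abs=1e-4)

    def test_coefficient_recovery(self, rng):
        beta = [0.8, -0.5, 0.3]
        X, y, _ = logistic_data(rng, 50_000, beta)
        model = fit_lr_main(X, y)
        # at this n the ML standard errors are ~0.015; 3 SEs with margin
        np.testing.assert_allclose(model.metadata["coef"], beta, atol=0.06)

    def test_empty_covariate_model_predicts_event_fraction(self, rng):
        y = (rng.random(200) < 0.3).astype(int)
        model = fit_lr_main(pd.DataFrame(index=range(200)), y)
        np.testing.assert_allclose(model.predict(pd.DataFrame(index=range(5))), y.mean())

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="both events"):
            fit_lr_main(X, np.zeros(3, dtype=int))


class TestLogisticSpline:
    def test_parameter_count(self, rng):
        X = pd.DataFrame(
            {
                "c1": rng.standard_normal(500),
                "c2": rng.standard_normal(500),
                "b1": rng.integers(0, 2, 500),
            }
        )
        y = (rng.random(500) < expit(X["c1"])).astype(int)
        model = fit_lr_spline(X, y, continuous=["c1", "c2"], df=4)
        # intercept + 1 binary + 4 basis columns per continuous
        assert model.metadata["n_params"] == 1 + 1 + 4 * 2

    def test_quadratic_truth_beats_linear_model(self, rng):
        n = 10_000
        x = rng.standard_normal(n)
        p = expit(-2.0 + 1.2 * (x * x - 1.0))
        y = (rng.random(n) < p).astype(int)
        X = pd.DataFrame({"x": x})
        m_lin = fit_lr_main(X, y)
        m_spl = fit_lr_spline(X, y, continuous=["x"])
        assert mape(m_spl.predict(X), p) < mape(m_lin.predict(X), p)

    def test_linear_truth_slope_near_one_at_large_n(self, rng):
        from predsize.metrics import calibration_slope

        X, y, _ = logistic_data(rng, 40_000, [0.9])
        model = fit_lr_spline(X, y, continuous=["x0"])
        # refit noise only: the spline model nests the linear truth
        X2, y2, _ = logistic_data(rng, 40_000, [0.9])
        slope = calibration_slope(model.predict(X2), y2)
        assert slope == pytest.approx(1.0, abs=0.1)


class TestTreeEnsembles:
    def test_bagging_single_tree_votes_zero_one(self, rng):
        X, y, _ = logistic_data(rng, 400, [1.0])
        model = fit_bagging(X, y, seed=0, n_trees=1)
        preds = model.predict(X)
        assert set(np.unique(preds)).issubset({0.0, 0.5, 1.0})

    def test_forest_with_full_subset_equals_bagging(self, rng):
        X, y, _ = logistic_data(rng, 600, [1.0, -0.7])
        bag = fit_bagging(X, y, seed=3, n_trees=15)
        forest = fit_random_forest(X, y, seed=3, n_trees=15, max_features=None)
        np.testing.assert_array_equal(bag.predict(X), forest.predict(X))

    def test_vote_fractions_live_on_tree_grid(self, rng):
        X, y, _ = logistic_data(rng, 500, [1.0])
        model = fit_random_forest(X, y, seed=1, n_trees=8)
        preds = model.predict(X)
        np.testing.assert_allclose((preds * 16) % 1, 0.0, atol=1e-12)  # halves allowed

    def test_boosting_initialises_at_event_log_odds(self, rng):
        X, y, _ = logistic_data(rng, 800, [1.0])
        model = fit_boosting(X, y, seed=0, n_trees=1, learning_rate=1e-9)
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-6)

    def test_boosting_strictly_interior(self, rng):
        X, y, _ = logistic_data(rng, 800, [1.5, 1.0])
        preds = fit_boosting(X, y, seed=0, n_trees=50).predict(X)
        assert preds.min() > 0.0 and preds.max() < 1.0

    def test_seed_determinism(self, rng):
        X, y, _ = logistic_data(rng, 400, [1.0])
        a = fit_model("random_forest", X, y, seed=11, hyperparameters={"n_trees": 10})
        b = fit_model("random_forest", X, y, seed=11, hyperparameters={"n_trees": 10})
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


class TestLargeSampleBehaviour:
    def test_lr_mape_shrinks_while_forest_plateaus(self, rng):
        # with a logistic main-effects truth, the matched model's error
        # vanishes with n while vote-proportion ensembles level off
        beta = [1.0, -0.8, 0.6]
        results = {}
        for n in (1_000, 8_000):
            X, y, p = logistic_data(rng, n, beta, intercept=-2.5)
            Xv, _, pv = logistic_data(rng, 4_000, beta, intercept=-2.5)
            results[("lr", n)] = mape(fit_lr_main(X, y).predict(Xv), pv)
            results[("rf", n)] = mape(
                fit_random_forest(X, y, seed=0, n_trees=30).predict(Xv), pv
            )
        assert results[("lr", 8_000)] < 0.5 * results[("lr", 1_000)]
        assert results[("rf", 8_000)] > 0.5 * results[("rf", 1_000)]
        assert results[("rf", 8_000)] > results[("lr", 8_000)]


class TestTuning:
    def make_datasets(self, rng, n_datasets=2, n=400):
        return [logistic_data(rng, n, [1.0, -0.5])[:2] for _ in range(n_datasets)]

    def test_grid_of_size_one(self, rng):
        datasets = self.make_datasets(rng)
        result = tune_hyperparameters(
            "random_forest", datasets, grid=[{"n_trees": 5}], folds=3, seed=0
        )
        assert result.best == {"n_trees": 5}

    def test_sane_point_beats_degenerate(self, rng):
        datasets = self.make_datasets(rng)
        grid = [
            {"n_trees": 1, "max_depth": 1, "learning_rate": 1e-7, "subsample": 0.5},
            {"n_trees": 60, "max_depth": 2, "learning_rate": 0.1, "subsample": 0.5},
        ]
        result = tune_hyperparameters("boosting", datasets, grid=grid, folds=3, seed=0)
        assert result.best["n_trees"] == 60

    def test_fixed_seed_identical_selection(self, rng):
        datasets = self.make_datasets(rng)
        grid = default_grid("random_forest", 2)[:4]
        a = tune_hyperparameters("random_forest", datasets, grid=grid, folds=3, seed=5)
        b = tune_hyperparameters("random_forest", datasets, grid=grid, folds=3, seed=5)
        assert a.best == b.best

    def test_empty_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            tune_hyperparameters("bagging", [], grid=[{}])
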