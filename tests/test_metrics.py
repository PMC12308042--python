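"""Tests for the validation-metric suite."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from predsize.metrics import (
    brier,
    c_statistic,
    calibration_in_the_large,
    calibration_slope,
    delong_se,
    e90,
    evaluate_all,
    ici,
    ici_weighted,
    mape,
)


def c_brute_force(p, y):
    """O(n^2) pair enumeration with ties counted a half."""
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def delong_brute_force(p, y):
    """Structural components computed pair-by-pair."""
    pos = p[y == 1]
    neg = p[y == 0]
    score = lambda a, b: 1.0 if a > b else (0.5 if a == b else 0.0)
    v10 = np.array([np.mean([score(a, b) for b in neg]) for a in pos])
    v01 = np.array([np.mean([score(a, b) for a in pos]) for b in neg])
    return np.sqrt(v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg))


class TestMape:
    def test_identical_is_zero(self, rng):
        p = rng.uniform(0, 1, 50)
        assert mape(p, p) == 0.0

    def test_constant_shift(self, rng):
        p = rng.uniform(0.1, 0.8, 50)
        assert mape(p + 0.05, p) == pytest.approx(0.05)

    def test_matches_hand_sum(self, rng):
        a = rng.uniform(0, 1, 7)
        b = rng.uniform(0, 1, 7)
        assert mape(a, b) == pytest.approx(sum(abs(x - y) for x, y in zip(a, b)) / 7)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mape(np.zeros(3), np.zeros(4))


class TestCStatistic:
    def test_perfect_separation(self):
        p = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        assert c_statistic(p, y) == 1.0

    def test_constant_predictions_half(self):
        assert c_statistic(np.full(10, 0.3), np.r_[np.ones(4), np.zeros(6)]) == 0.5

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        p = np.round(rng.uniform(0, 1, n), 1)  # rounding forces ties
        y = rng.integers(0, 2, n)
        if 0 < y.sum() < n:
            assert c_statistic(p, y) == pytest.approx(c_brute_force(p, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_statistic(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0, 1, 80)
        y = rng.integers(0, 2, 80)
        perm = rng.permutation(80)
        assert c_statistic(p, y) == pytest.approx(c_statistic(p[perm], y[perm]))


class TestDeLong:
    def test_matches_brute_force_small(self, rng):
        p = np.round(rng.uniform(0, 1, 12), 1)
        y = np.r_[np.ones(5, int), np.zeros(7, int)]
        assert delong_se(p, y) == pytest.approx(delong_brute_force(p, y), abs=1e-12)

    def test_three_vs_three_hand_values(self):
        # pos scores (0.9, 0.8, 0.4), neg scores (0.7, 0.3, 0.2):
        # V10 = (1, 2/3, 2/3), V01 = (2/3, 1, 1) -> var terms 1/27 each
        p = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
        y = np.array([1, 1, 1, 0, 0, 0])
        expected = np.sqrt((1.0 / 27.0) / 3 + (1.0 / 27.0) / 3)
        assert delong_se(p, y) == pytest.approx(expected, abs=1e-12)

    def test_duplication_shrinks_se_by_sqrt2(self, rng):
        p = rng.uniform(0, 1, 400)
        y = (rng.random(400) < p).astype(int)
        ratio = delong_se(np.r_[p, p], np.r_[y, y]) / delong_se(p, y)
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_positive_when_nondegenerate(self, rng):
        p = rng.uniform(0, 1, 50)
        y = rng.integers(0, 2, 50)
        if 2 <= y.sum() <= 48:
            assert delong_se(p, y) > 0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            delong_se(np.array([0.1, 0.2, 0.3]), np.array([1, 0, 0]))


class TestCalibrationInTheLarge:
    def test_matched_means_zero(self, rng):
        p = rng.uniform(0, 1, 100)
        y = rng.integers(0, 2, 100)
        shifted = p + (y.mean() - p.mean())
        assert calibration_in_the_large(shifted, y) == pytest.approx(0.0, abs=1e-12)

    def test_overestimation_is_negative(self):
        y = np.r_[np.ones(10, int), np.zeros(90, int)]
        assert calibration_in_the_large(np.full(100, 0.15), y) == pytest.approx(-0.05)

    def test_worked_vector(self):
        p = np.array([0.2, 0.4, 0.6])
        y = np.array([0, 1, 1])
        assert calibration_in_the_large(p, y) == pytest.approx(2 / 3 - 0.4)


class TestCalibrationSlope:
    def test_true_model_slope_one(self, rng):
        p = expit(rng.normal(-1.5, 1.2, 100_000))
        y = (rng.random(p.size) < p).astype(int)
        assert calibration_slope(p, y) == pytest.approx(1.0, abs=0.05)

    def test_doubled_logit_slope_half(self, rng):
        p_true = expit(rng.normal(-1.5, 1.2, 100_000))
        y = (rng.random(p_true.size) < p_true).astype(int)
        p_over = expit(2 * logit(p_true))
        assert calibration_slope(p_over, y) == pytest.approx(0.5, abs=0.05)

    def test_constant_predictions_missing(self):
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        assert np.isnan(calibration_slope(np.full(40, 0.4), y))


class TestCalibrationCurveMetrics:
    def test_calibrated_by_construction(self, rng):
        p = rng.uniform(0.05, 0.9, 100_000)
        y = (rng.random(p.size) < p).astype(int)
        assert ici(p, y) < 0.01
        assert e90(p, y) < 0.02

    def test_detects_injected_shift(self, rng):
        p_true = rng.uniform(0.1, 0.8, 100_000)
        y = (rng.random(p_true.size) < p_true).astype(int)
        assert ici(p_true + 0.10, y) == pytest.approx(0.10, abs=0.01)

    def test_e90_at_least_median_error(self, rng):
        p = rng.uniform(0.1, 0.9, 5_000)
        y = (rng.random(p.size) < np.clip(p + 0.05, 0, 1)).astype(int)
        from predsize.metrics import _calibration_abs_errors

        errors = _calibration_abs_errors(p, y)
        assert e90(p, y) >= np.median(errors)

    def test_weighted_variant_on_hand_vector(self):
        p = np.array([0.2, 0.5])
        y = np.array([0, 1])
        expected = (0.2 * 0.2 + 0.5 * 0.5) / 0.7
        assert ici_weighted(p, y) == pytest.approx(expected)


class TestBrier:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        assert brier(y.astype(float), y) == 0.0

    def test_constant_at_prevalence(self, rng):
        y = (rng.random(10_000) < 0.3).astype(int)
        p_const = np.full(y.size, y.mean())
        assert brier(p_const, y) == pytest.approx(y.mean() * (1 - y.mean()), abs=1e-12)

    def test_worked_vector(self):
        p = np.array([0.1, 0.8])
        y = np.array([0, 1])
        assert brier(p, y) == pytest.approx((0.01 + 0.04) / 2)


class TestEvaluateAll:
    def test_interior_predictions_are_passthrough(self, rng):
        p = rng.uniform(0.05, 0.95, 2_000)
        pi = rng.uniform(0.05, 0.95, 2_000)
        y = (rng.random(2_000) < pi).astype(int)
        ms = evaluate_all(p, pi, y)
        assert ms.n_excluded_boundary == 0
        assert ms.mape == pytest.approx(mape(p, pi))
        assert ms.c_statistic == pytest.approx(c_statistic(p, y))
        assert ms.brier == pytest.approx(brier(p, y))

    def test_boundary_predictions_clipped_and_excluded(self, rng):
        p = rng.uniform(0.2, 0.8, 1_000)
        p[:100] = 0.0
        p[100:150] = 1.0
        pi = rng.uniform(0.1, 0.9, 1_000)
        y = (rng.random(1_000) < pi).astype(int)
        ms = evaluate_all(p, pi, y)
        assert ms.n_excluded_boundary == 150
        clipped = np.clip(p, 1e-4, 1 - 1e-4)
        assert ms.c_statistic == pytest.approx(c_statistic(clipped, y))
        interior = (p > 0) & (p < 1)
        assert ms.citl == pytest.approx(
            calibration_in_the_large(p[interior], y[interior])
        )

    def test_all_boundary_calibration_missing(self):
        p = np.r_[np.zeros(30), np.ones(10)]
        y = np.r_[np.zeros(30, int), np.ones(10, int)]
        pi = np.full(40, 0.25)
        ms = evaluate_all(p, pi, y)
        assert np.isnan(ms.cal_slope) and np.isnan(ms.citl)
        assert "cal_slope" in ms.reasons
        assert np.isfinite(ms.mape) and np.isfinite(ms.brier)

    def test_metric_subset_skips_the_rest(self, rng):
        p = rng.uniform(0.1, 0.9, 500)
        y = rng.integers(0, 2, 500)
        ms = evaluate_all(p, None, y, metrics=("brier",))
        assert np.isfinite(ms.brier)
        assert np.isnan(ms.c_statistic) and np.isnan(ms.ici)
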