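"""Tests for the synthetic cohort generator and its calibration machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from predsize.synthetic_cohort import (
    Cohort,
    Predictor,
    PredictorSchema,
    calibrate_discrimination,
    calibrate_intercept,
    expected_c_of_probabilities,
    generate_covariates,
    hf_like_surface,
    minap_like_schema,
    minap_like_surface,
    simulate_outcomes,
)


def expected_c_brute_force(pi):
    """O(N^2) enumeration of the expected concordance."""
    num = den = 0.0
    for i, pi_i in enumerate(pi):
        for j, pi_j in enumerate(pi):
            if i == j:
                continue
            w = pi_i * (1 - pi_j)
            den += w
            if pi_i > pi_j:
                num += w
            elif pi_i == pi_j:
                num += 0.5 * w
    return num / den


class TestGenerateCovariates:
    def test_same_seed_identical(self):
        schema = minap_like_schema()
        a = generate_covariates(schema, 500, seed=9)
        b = generate_covariates(schema, 500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_independent_binaries_uncorrelated(self):
        schema = PredictorSchema(
            (Predictor("b1", "binary", prevalence=0.5), Predictor("b2", "binary", prevalence=0.5)),
            np.eye(2),
        )
        X = generate_covariates(schema, 100_000, seed=1)
        r = np.corrcoef(X["b1"], X["b2"])[0, 1]
        assert abs(r) < 0.02

    def test_latent_correlation_recovered_for_continuous(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        schema = PredictorSchema(
            (Predictor("c1", "continuous"), Predictor("c2", "continuous")), corr
        )
        X = generate_covariates(schema, 100_000, seed=2)
        r = np.corrcoef(X["c1"], X["c2"])[0, 1]
        assert r == pytest.approx(0.6, abs=0.02)

    def test_marginals_match_declarations(self):
        schema = minap_like_schema()
        X = generate_covariates(schema, 50_000, seed=3)
        assert X["bin2"].mean() == pytest.approx(0.30, abs=0.01)
        assert X["cont1"].std() == pytest.approx(1.0, abs=0.02)
        levels, counts = np.unique(X["ord1"], return_counts=True)
        assert list(levels) == [0, 1, 2]
        assert counts[0] / len(X) == pytest.approx(0.5, abs=0.01)

    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        schema = PredictorSchema(
            tuple(Predictor(f"c{i}", "continuous") for i in range(3)), bad
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_covariates(schema, 10, seed=0)


class TestCalibrateIntercept:
    def test_zero_lp_half_target(self):
        assert calibrate_intercept(np.zeros(100), 0.5) == pytest.approx(0.0, abs=1e-8)

    def test_zero_lp_closed_form(self):
        b0 = calibrate_intercept(np.zeros(100), 0.063)
        assert b0 == pytest.approx(logit(0.063), abs=1e-8)

    def test_postcondition_on_noisy_lp(self, rng):
        lp = rng.standard_normal(20_000)
        b0 = calibrate_intercept(lp, 0.113)
        assert np.mean(expit(b0 + lp)) == pytest.approx(0.113, abs=1e-4)


class TestExpectedC:
    def test_all_equal_is_half(self):
        assert expected_c_of_probabilities(np.full(10, 0.3)) == pytest.approx(0.5)

    def test_two_subject_closed_form(self):
        assert expected_c_of_probabilities(np.array([0.9, 0.1])) == pytest.approx(
            0.81 / (0.81 + 0.01)
        )

    def test_matches_brute_force(self, rng):
        pi = rng.uniform(0.01, 0.99, size=50)
        pi[5] = pi[10]  # force a tie
        assert expected_c_of_probabilities(pi) == pytest.approx(
            expected_c_brute_force(pi), abs=1e-12
        )

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            expected_c_of_probabilities(np.zeros(5))


class TestCalibrateDiscrimination:
    def test_minap_surface_hits_target(self, minap_cohort_20k):
        c = expected_c_of_probabilities(minap_cohort_20k.pi)
        assert c == pytest.approx(0.86, abs=0.01)
        assert minap_cohort_20k.expected_prevalence == pytest.approx(0.063, abs=1e-3)

    def test_hf_surface_hits_target(self, hf_cohort_20k):
        c = expected_c_of_probabilities(hf_cohort_20k.pi)
        assert c == pytest.approx(0.81, abs=0.01)
        assert hf_cohort_20k.expected_prevalence == pytest.approx(0.113, abs=1e-3)

    def test_hf_surface_has_nonlinear_transforms(self):
        surface = hf_like_surface()
        non_identity = [t for t in surface.transforms.values() if t != "identity"]
        assert len(non_identity) >= 4

    def test_scale_monotone_in_achieved_c(self):
        schema = minap_like_schema()
        X = generate_covariates(schema, 5_000, seed=4)
        surface = minap_like_surface()
        achieved = []
        for scale in (0.25, 0.5, 1.0, 2.0):
            lp = scale * type(surface)(
                coefficients=surface.coefficients,
                target_prevalence=surface.target_prevalence,
                target_c=surface.target_c,
            ).linear_predictor(X)
            b0 = calibrate_intercept(lp, 0.063)
            achieved.append(expected_c_of_probabilities(expit(b0 + lp)))
        assert achieved == sorted(achieved)

    def test_unattainable_target_warns(self):
        schema = PredictorSchema((Predictor("b", "binary", prevalence=0.5),), np.eye(1))
        X = generate_covariates(schema, 2_000, seed=5)
        # a single binary predictor cannot discriminate to C = 0.95
        from predsize.synthetic_cohort import TruthSurfaceSpec

        spec = TruthSurfaceSpec(
            coefficients={"b": 1.0}, target_prevalence=0.3, target_c=0.95
        )
        with pytest.warns(UserWarning, match="unattainable"):
            calibrate_discrimination(spec, X, max_scale=8.0)


class TestSimulateOutcomes:
    def test_deterministic_extremes(self):
        assert simulate_outcomes(np.zeros(50), seed=1).sum() == 0
        assert simulate_outcomes(np.ones(50), seed=1).sum() == 50

    def test_mean_concentrates(self, rng):
        pi = rng.uniform(0, 1, 100_000)
        y = simulate_outcomes(pi, seed=2)
        sd = np.sqrt(np.mean(pi * (1 - pi)) / len(pi))
        assert abs(y.mean() - pi.mean()) < 3 * sd


class TestCohort:
    def test_same_seed_bit_identical(self):
        from predsize.synthetic_cohort import make_cohort

        a = make_cohort("minap", n=1_000, seed=42)
        b = make_cohort("minap", n=1_000, seed=42)
        pd.testing.assert_frame_equal(a.X, b.X)
        np.testing.assert_array_equal(a.pi, b.pi)
        np.testing.assert_array_equal(a.y, b.y)

    def test_realized_prevalence_near_target(self, minap_cohort_20k, hf_cohort_20k):
        assert minap_cohort_20k.prevalence == pytest.approx(0.063, abs=0.005)
        assert hf_cohort_20k.prevalence == pytest.approx(0.113, abs=0.005)

    def test_roundtrip_write(self, tmp_path, minap_cohort_small):
        table = tmp_path / "cohort.csv"
        sidecar = tmp_path / "cohort.json"
        minap_cohort_small.write(str(table), str(sidecar))
        back = pd.read_csv(table)
        assert "y" in back.columns and "pi_true" in back.columns
        assert len(back) == len(minap_cohort_small)
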