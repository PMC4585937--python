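"""Unit and property tests of the closed-form Bayesian observer."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from tactile_filehne.observer import (
    Z75,
    ObserverParams,
    calibrate_prior_variance,
    filehne_gain,
    fused_distribution,
    jnd_from_slope,
    perceived_velocity_biased,
    predicted_psychometric,
    predicted_unimodal_slope,
    response_probability,
    shrinkage_weight,
)

variances = st.floats(min_value=1e-2, max_value=1e3)


class TestShrinkageWeight:
    def test_symmetry_and_limits(self):
        post = shrinkage_weight(1.0, 1.0)
        assert post.weight == pytest.approx(0.5)
        assert post.post_var == pytest.approx(0.5)
        # noiseless likelihood dominates the prior
        tiny = shrinkage_weight(1.0, 1e-12)
        assert tiny.weight == pytest.approx(1.0)
        assert tiny.post_var == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -1.0, -1e-9])
    def test_rejects_nonpositive_variance(self, bad):
        with pytest.raises(ValueError):
            shrinkage_weight(bad, 1.0)
        with pytest.raises(ValueError):
            shrinkage_weight(1.0, bad)

    @given(variances, variances, variances)
    def test_weight_decreasing_in_likelihood_variance(self, s2p, s2a, s2b):
        lo, hi = sorted([s2a, s2b])
        if lo == hi:
            return
        assert shrinkage_weight(s2p, lo).weight > shrinkage_weight(s2p, hi).weight

    def test_conjugate_gaussian_sampling_oracle(self, rng):
        """Posterior-mean shrinkage matches brute-force conjugate sampling."""
        s2_prior, s2_like, m = 0.4753, 34.0, 5.0
        post = shrinkage_weight(s2_prior, s2_like)
        # importance-free oracle: sample v ~ prior, accept-weight by likelihood
        v = rng.normal(0.0, math.sqrt(s2_prior), size=1_000_000)
        w_is = norm.pdf(m, loc=v, scale=math.sqrt(s2_like))
        post_mean = np.average(v, weights=w_is)
        # standard error of a self-normalised importance-sampling mean
        se = math.sqrt((w_is**2 * (v - post_mean) ** 2).sum()) / w_is.sum()
        assert abs(post_mean - post.weight * m) < 3 * se
        assert post.weight == pytest.approx(0.01379, rel=1e-3)


class TestFusedDistribution:
    def test_equal_weights_cancel_for_stationary_surface(self):
        p = ObserverParams.single_prior(1.0, 5.0, 5.0, v_pursuit=10.0)
        assert fused_distribution(p, 0.0).mean == pytest.approx(0.0)

    def test_without_proprioception_stationary_is_unbiased(self):
        p = ObserverParams.single_prior(1.0, 5.0, 7.0)
        assert fused_distribution(p, 0.0, proprioception_active=False).mean == 0.0

    def test_stationary_surface_appears_to_move_backwards(self, calibrated_params):
        fused = fused_distribution(calibrated_params, 0.0, 10.8)
        assert fused.mean < 0.0

    def test_two_stage_sampling_oracle(self, calibrated_params, rng):
        """Closed-form mean/sd match measurement->posterior->sum sampling."""
        p, n = calibrated_params, 1_000_000
        wp = p.sigma2_prior_prop / (p.sigma2_prior_prop + p.sigma2_prop)
        wt = p.sigma2_prior_tact / (p.sigma2_prior_tact + p.sigma2_tact)
        v_prop, v_surf = 10.8, 0.0
        m_p = rng.normal(v_prop, math.sqrt(p.sigma2_prop), n)
        m_t = rng.normal(v_surf - v_prop, math.sqrt(p.sigma2_tact), n)
        draw_p = rng.normal(wp * m_p, math.sqrt(wp * p.sigma2_prop))
        draw_t = rng.normal(wt * m_t, math.sqrt(wt * p.sigma2_tact))
        total = draw_p + draw_t
        fused = fused_distribution(p, v_surf, v_prop)
        assert fused.mean == pytest.approx(total.mean(), abs=3 * total.std() / math.sqrt(n))
        assert fused.sd == pytest.approx(total.std(), rel=5e-3)


class TestResponseProbability:
    def test_half_at_predicted_pse(self, calibrated_params):
        pse = predicted_psychometric(calibrated_params, "main").pse
        assert response_probability(calibrated_params, pse, 10.8) == pytest.approx(0.5, abs=1e-12)

    def test_saturates_for_fast_surfaces(self, calibrated_params):
        assert response_probability(calibrated_params, 1e4, 10.8) == pytest.approx(1.0)

    @given(st.floats(-25, 25), st.floats(-25, 25))
    def test_strictly_increasing_in_surface_velocity(self, va, vb):
        p = ObserverParams.single_prior(0.5, 20.0, 8.0)
        lo, hi = sorted([va, vb])
        if hi - lo < 1e-6:
            return
        assert response_probability(p, lo, 10.8) < response_probability(p, hi, 10.8)

    def test_matches_simulated_binary_responses(self, calibrated_params, rng):
        p, n = calibrated_params, 100_000
        for v_surf in (-10.0, 0.0, 5.0):
            prob = response_probability(p, v_surf, 10.8)
            wp = p.sigma2_prior_prop / (p.sigma2_prior_prop + p.sigma2_prop)
            wt = p.sigma2_prior_tact / (p.sigma2_prior_tact + p.sigma2_tact)
            m_p = rng.normal(10.8, math.sqrt(p.sigma2_prop), n)
            m_t = rng.normal(v_surf - 10.8, math.sqrt(p.sigma2_tact), n)
            est = rng.normal(wp * m_p, math.sqrt(wp * p.sigma2_prop)) + rng.normal(
                wt * m_t, math.sqrt(wt * p.sigma2_tact)
            )
            frac = (est > 0).mean()
            se = math.sqrt(prob * (1 - prob) / n)
            assert abs(frac - prob) < 3 * se


class TestPredictedPsychometric:
    @given(variances, variances, variances, st.floats(1.0, 30.0))
    def test_control_pse_always_zero(self, s2s, s2p, s2t, v):
        params = ObserverParams.single_prior(s2s, s2p, s2t, v_pursuit=v)
        psy = predicted_psychometric(params, "control")
        assert psy.pse == 0.0
        assert psy.intercept == 0.0

    def test_no_noise_asymmetry_no_illusion(self):
        p = ObserverParams.single_prior(0.7, 9.0, 9.0, v_pursuit=10.8)
        assert predicted_psychometric(p, "main").pse == pytest.approx(0.0, abs=1e-12)

    def test_calibrated_parameters_reproduce_reference_pse(self, calibrated_params):
        psy = predicted_psychometric(calibrated_params, "main")
        assert psy.pse == pytest.approx(7.2, abs=0.05)

    @given(variances, variances, variances, st.floats(1.0, 30.0))
    def test_pse_is_minus_intercept_over_slope(self, s2s, s2p, s2t, v):
        params = ObserverParams.single_prior(s2s, s2p, s2t, v_pursuit=v)
        psy = predicted_psychometric(params, "main")
        assert psy.pse == pytest.approx(-psy.intercept / psy.slope, rel=1e-9, abs=1e-9)
        assert psy.jnd == pytest.approx(Z75 / psy.slope, rel=1e-12)

    def test_zero_pursuit_degenerates_to_control(self):
        p = ObserverParams.single_prior(0.5, 20.0, 8.0, v_pursuit=0.0)
        assert predicted_psychometric(p, "main").pse == 0.0

    def test_illusion_grows_with_proprioceptive_noise(self):
        pses = [
            predicted_psychometric(
                ObserverParams.single_prior(0.5, s2p, 8.0, v_pursuit=10.8), "main"
            ).pse
            for s2p in (10.0, 20.0, 40.0, 80.0)
        ]
        assert np.all(np.diff(pses) > 0)

    def test_illusion_shrinks_with_tactile_noise(self):
        pses = [
            predicted_psychometric(
                ObserverParams.single_prior(0.5, 40.0, s2t, v_pursuit=10.8), "main"
            ).pse
            for s2t in (5.0, 10.0, 20.0, 40.0)
        ]
        assert np.all(np.diff(pses) < 0)

    @given(variances, st.floats(0.1, 10.0))
    def test_variance_scale_invariance(self, s2t, c):
        """Scaling all variances by c preserves weights and PSE, divides slopes by sqrt(c)."""
        base = ObserverParams.single_prior(0.5, 30.0, s2t, v_pursuit=10.8)
        scaled = ObserverParams.single_prior(0.5 * c, 30.0 * c, s2t * c, v_pursuit=10.8)
        for cond in ("main", "control"):
            a, b = predicted_psychometric(base, cond), predicted_psychometric(scaled, cond)
            assert b.pse == pytest.approx(a.pse, rel=1e-9, abs=1e-9)
            assert b.slope == pytest.approx(a.slope / math.sqrt(c), rel=1e-9)


class TestUnimodalSlope:
    def test_reference_slopes(self, calibrated_params):
        s2s = calibrated_params.sigma2_prior_prop
        assert predicted_unimodal_slope(s2s, 34.0) == pytest.approx(0.02, abs=1e-4)
        assert predicted_unimodal_slope(s2s, 11.0) == pytest.approx(0.06, abs=1e-3)

    @given(variances, variances, variances)
    def test_decreasing_in_likelihood_variance(self, s2s, a, b):
        lo, hi = sorted([a, b])
        if lo == hi:
            return
        assert predicted_unimodal_slope(s2s, lo) > predicted_unimodal_slope(s2s, hi)

    def test_matches_simulated_unimodal_refit(self, rng):
        """Predicted slope agrees with a probit refit of simulated responses."""
        from tactile_filehne.psychometrics import batch_probit_counts

        s2s, s2 = 0.4753, 11.0
        slope = predicted_unimodal_slope(s2s, s2)
        w = s2s / (s2s + s2)
        levels = np.linspace(-30, 30, 13)
        n_per = 8000
        m = rng.normal(levels[None, :], math.sqrt(s2), size=(n_per, 13))
        est = rng.normal(w * m, math.sqrt(w * s2))
        k = (est > 0).sum(axis=0)
        X = np.column_stack([np.ones_like(levels), levels])
        beta, _ = batch_probit_counts(k[None, :].astype(float), float(n_per), X)
        fitted = beta[0, 1]
        # binomial-information SE of the fitted slope
        p = norm.cdf(slope * levels)
        info = (n_per * norm.pdf(slope * levels) ** 2 / (p * (1 - p)) * levels**2).sum()
        assert abs(fitted - slope) < 2.5 / math.sqrt(info)


class TestCalibration:
    def test_reference_value(self):
        assert calibrate_prior_variance(0.02, 34.0) == pytest.approx(0.475, abs=1e-3)

    @given(st.floats(0.005, 0.1), variances)
    def test_round_trip_identity(self, slope, s2):
        if slope**2 * s2 >= 0.5 * 0.98:
            return
        s2s = calibrate_prior_variance(slope, s2)
        assert predicted_unimodal_slope(s2s, s2) == pytest.approx(slope, abs=1e-10)

    def test_unattainable_slope_rejected(self):
        s2 = 34.0
        upper = 1.0 / math.sqrt(2 * s2)
        with pytest.raises(ValueError):
            calibrate_prior_variance(upper, s2)
        with pytest.raises(ValueError):
            calibrate_prior_variance(0.0, s2)


class TestScalars:
    def test_jnd_values(self):
        assert jnd_from_slope(0.02) == pytest.approx(33.75, rel=1e-3)
        assert jnd_from_slope(0.06) == pytest.approx(11.25, rel=1e-3)
        assert jnd_from_slope(Z75) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            jnd_from_slope(0.0)

    def test_filehne_gain(self):
        assert round(filehne_gain(6.8, 10.8), 1) == 0.4
        assert filehne_gain(0.0, 10.8) == pytest.approx(1.0)
        assert filehne_gain(10.8, 10.8) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            filehne_gain(5.0, 0.0)

    def test_biased_summation(self):
        # gain 1 recovers ideal world-centred summation
        assert perceived_velocity_biased(-4.0, 10.0, 1.0) == pytest.approx(6.0)
        # stationary surface, gain < 1: perceived motion opposite the hand
        out = perceived_velocity_biased(-10.8, 10.8, 0.6)
        assert out == pytest.approx(-4.32)
        assert out < 0
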