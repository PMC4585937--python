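"""Tests of probit fitting, PSE/JND extraction, bootstrap and LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from tactile_filehne.psychometrics import (
    batch_probit_counts,
    bootstrap_probit_pse,
    fit_discrimination,
    fit_probit_ml,
    lrt_slopes,
)
from tactile_filehne.synth import make_design, simulate_binomial_from_probit, simulate_population, PopulationSpec


def _binary_trials(b0, b1, velocities, reps, seed):
    rng = np.random.default_rng(seed)
    v = np.repeat(np.asarray(velocities, dtype=float), reps)
    y = (rng.random(len(v)) < norm.cdf(b0 + b1 * v)).astype(int)
    return pd.DataFrame({"v_surf": v, "response": y})


def _grid_search_probit(counts, b0_range, b1_range, rounds=6, width=121):
    """Independent nested grid-search maximiser of the Bernoulli likelihood."""
    v = counts["v_surf"].to_numpy(float)
    n = counts["n"].to_numpy(float)
    k = counts["k"].to_numpy(float)

    def nll(b0, b1):
        p = np.clip(norm.cdf(b0 + b1 * v), 1e-12, 1 - 1e-12)
        return -(k * np.log(p) + (n - k) * np.log(1 - p)).sum()

    lo = np.array([b0_range[0], b1_range[0]])
    hi = np.array([b0_range[1], b1_range[1]])
    for _ in range(rounds):
        g0 = np.linspace(lo[0], hi[0], width)
        g1 = np.linspace(lo[1], hi[1], width)
        vals = np.array([[nll(a, b) for b in g1] for a in g0])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        span = (hi - lo) / (width - 1)
        centre = np.array([g0[i], g1[j]])
        lo, hi = centre - 3 * span, centre + 3 * span
    return centre


class TestFitProbitML:
    def test_matches_grid_search_oracle(self):
        counts = simulate_binomial_from_probit(-0.3, 0.05, [-30, -15, 0, 15, 30], 25, seed=11)
        fit = fit_probit_ml(counts)
        oracle = _grid_search_probit(counts, (-2.0, 2.0), (-0.2, 0.3))
        assert fit.intercept == pytest.approx(oracle[0], abs=1e-4)
        assert fit.slope == pytest.approx(oracle[1], abs=1e-4)

    def test_recovers_individual_observer_pses(self):
        # generative truths shaped like a strongly biased single observer:
        # control PSE -1.5 mm/s, main PSE 11.5 mm/s
        b1c, b1m = 0.06, 0.045
        ctrl = _binary_trials(1.5 * b1c, b1c, [-30, -20, -10, 10, 20, 30], 40, seed=1)
        main = _binary_trials(-11.5 * b1m, b1m, [-30, -20, -10, 0, 10, 20, 30], 40, seed=2)
        fc, fm = fit_probit_ml(ctrl), fit_probit_ml(main)
        assert fc.pse == pytest.approx(-1.5, abs=2 * fc.pse_se)
        assert fm.pse == pytest.approx(11.5, abs=2 * fm.pse_se)

    def test_constant_response_rejected(self):
        trials = pd.DataFrame({"v_surf": [-10.0, 0.0, 10.0] * 5, "response": 1})
        with pytest.raises(ValueError, match="constant"):
            fit_probit_ml(trials)

    def test_complete_separation_flagged(self):
        trials = pd.DataFrame(
            {"v_surf": [-20.0] * 10 + [20.0] * 10, "response": [0] * 10 + [1] * 10}
        )
        fit = fit_probit_ml(trials)
        assert fit.separation
        assert np.isinf(fit.slope) and fit.slope > 0

    def test_needs_two_levels(self):
        trials = pd.DataFrame({"v_surf": [5.0] * 20, "response": [0, 1] * 10})
        with pytest.raises(ValueError, match="levels"):
            fit_probit_ml(trials)

    def test_delta_method_ses_finite(self):
        counts = simulate_binomial_from_probit(-0.3, 0.05, [-30, -15, 0, 15, 30], 30, seed=5)
        fit = fit_probit_ml(counts)
        assert fit.pse_se > 0 and np.isfinite(fit.pse_se)
        assert fit.jnd_se > 0 and np.isfinite(fit.jnd_se)
        assert fit.pse == pytest.approx(-fit.intercept / fit.slope)

    def test_units_rescale_consistently(self):
        """cm/s instead of mm/s: slope x10, PSE and JND /10, same fit quality."""
        counts = simulate_binomial_from_probit(-0.3, 0.05, [-30, -15, 0, 15, 30], 50, seed=6)
        fit_mm = fit_probit_ml(counts)
        counts_cm = counts.assign(v_surf=counts["v_surf"] / 10.0)
        fit_cm = fit_probit_ml(counts_cm)
        assert fit_cm.slope == pytest.approx(10 * fit_mm.slope, rel=1e-6)
        assert fit_cm.pse == pytest.approx(fit_mm.pse / 10, rel=1e-6)
        assert fit_cm.jnd == pytest.approx(fit_mm.jnd / 10, rel=1e-6)
        assert fit_cm.loglik == pytest.approx(fit_mm.loglik, abs=1e-6)


class TestBatchFitter:
    def test_matches_statsmodels_single_fit(self):
        counts = simulate_binomial_from_probit(0.2, 0.04, [-30, -10, 0, 10, 30], 40, seed=7)
        reference = fit_probit_ml(counts)
        v = counts["v_surf"].to_numpy(float)
        X = np.column_stack([np.ones_like(v), v])
        beta, ll = batch_probit_counts(
            counts["k"].to_numpy(float)[None, :], counts["n"].to_numpy(float), X
        )
        assert beta[0, 0] == pytest.approx(reference.intercept, abs=1e-6)
        assert beta[0, 1] == pytest.approx(reference.slope, abs=1e-6)
        assert ll[0] == pytest.approx(reference.loglik, abs=1e-6)

    def test_vectorised_over_replicates(self):
        rng = np.random.default_rng(8)
        v = np.array([-20.0, -10.0, 0.0, 10.0, 20.0])
        k = rng.binomial(30, norm.cdf(0.1 + 0.05 * v), size=(50, 5)).astype(float)
        X = np.column_stack([np.ones_like(v), v])
        beta, _ = batch_probit_counts(k, 30.0, X)
        assert beta.shape == (50, 2)
        assert np.median(beta[:, 1]) == pytest.approx(0.05, abs=0.01)


class TestDiscrimination:
    def test_symmetric_design_has_zero_point_of_equality(self):
        deltas = [-12, -8, -4, 0, 4, 8, 12]
        trials = _binary_trials(0.0, 0.11, deltas, 60, seed=9)
        fit = fit_discrimination(trials)
        assert abs(fit.pse) < 3 * fit.pse_se
        assert fit.jnd == pytest.approx(norm.ppf(0.75) / 0.11, rel=0.25)

    def test_noiseless_observer_is_flagged_as_separation(self):
        deltas = np.array([-8.0, -4.0, 4.0, 8.0])
        trials = pd.DataFrame(
            {"v_surf": np.repeat(deltas, 10), "response": np.repeat((deltas > 0).astype(int), 10)}
        )
        fit = fit_discrimination(trials)
        assert fit.separation


class TestLRT:
    def test_identical_models_give_null_result(self):
        counts = simulate_binomial_from_probit(0.0, 0.05, [-20, 0, 20], 30, seed=10)
        fit = fit_probit_ml(counts)
        stat, df, p = lrt_slopes(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_mismatched_data_rejected(self):
        a = fit_probit_ml(simulate_binomial_from_probit(0.0, 0.05, [-20, 0, 20], 30, seed=1))
        b = fit_probit_ml(simulate_binomial_from_probit(0.0, 0.05, [-20, 0, 20], 40, seed=1))
        with pytest.raises(ValueError):
            lrt_slopes(a, b)


class TestProbitBootstrap:
    def test_single_rep_is_degenerate(self):
        r = bootstrap_probit_pse(-0.3, 0.05, [-30, 0, 30], 20, n_reps=1, seed=1)
        assert r.ci_low == r.ci_high == r.replicates[0]

    def test_interval_brackets_truth_at_moderate_n(self):
        r = bootstrap_probit_pse(-0.34, 0.05, [-30, -20, -10, 0, 10, 20, 30], 15, n_reps=500, seed=2)
        assert r.ci_low < 6.8 < r.ci_high
        assert r.n_failed == 0
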