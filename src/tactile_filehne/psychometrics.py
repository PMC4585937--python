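"""Descriptive psychometric analysis: probit fits, PSE/JND, bootstrap, LRT.

The psychometric function is the probit model

    P(Y = 1 | v) = Phi(b0 + b1 * v),

with PSE = -b0/b1 (velocity of indifference) and JND = Phi^-1(0.75)/b1.
Per-observer fits go through statsmodels; a vectorised Newton fitter on
aggregated counts backs the parametric-bootstrap loops, where thousands of
refits are needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln
from scipy.stats import chi2, norm

from .observer import Z75

__all__ = [
    "BootstrapResult",
    "PsychometricFit",
    "aggregate_counts",
    "bootstrap_probit_pse",
    "fit_discrimination",
    "fit_probit_ml",
    "lrt_slopes",
]

_PCLIP = 1e-12


@dataclass
class PsychometricFit:
    """Maximum-likelihood probit fit for one observer/condition."""

    intercept: float
    slope: float
    cov_params: np.ndarray  # 2x2 covariance of (intercept, slope)
    loglik: float
    n_trials: int
    n_params: int = 2
    converged: bool = True
    separation: bool = False

    @property
    def se_intercept(self) -> float:
        return float(np.sqrt(self.cov_params[0, 0]))

    @property
    def se_slope(self) -> float:
        return float(np.sqrt(self.cov_params[1, 1]))

    @property
    def pse(self) -> float:
        return -self.intercept / self.slope

    @property
    def jnd(self) -> float:
        return Z75 / self.slope

    @property
    def pse_se(self) -> float:
        """Delta-method standard error of the PSE."""
        b0, b1 = self.intercept, self.slope
        grad = np.array([-1.0 / b1, b0 / b1**2])
        return float(np.sqrt(grad @ self.cov_params @ grad))

    @property
    def jnd_se(self) -> float:
        """Delta-method standard error of the JND."""
        return float(Z75 / self.slope**2 * np.sqrt(self.cov_params[1, 1]))


@dataclass
class BootstrapResult:
    """Percentile bootstrap summary of a scalar estimate."""

    estimate: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    n_reps: int
    n_failed: int = 0
    seed: int | None = None

    @property
    def significant(self) -> bool:
        """True when the 95% interval excludes zero."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


def aggregate_counts(trials: pd.DataFrame, velocity_col: str = "v_surf") -> pd.DataFrame:
    """Collapse binary trials to per-velocity (n, k) counts."""
    g = trials.groupby(velocity_col)["response"].agg(["count", "sum"]).reset_index()
    return g.rename(columns={velocity_col: "v_surf", "count": "n", "sum": "k"})


def _check_separation(v: np.ndarray, k: np.ndarray, n: np.ndarray) -> bool:
    """Complete separation: some velocity splits all 0s from all 1s."""
    has0 = v[k < n]
    has1 = v[k > 0]
    if len(has0) == 0 or len(has1) == 0:
        return True
    return has0.max() < has1.min() or has1.max() < has0.min()


def fit_probit_ml(trials: pd.DataFrame, velocity_col: str = "v_surf") -> PsychometricFit:
    """Fit the probit psychometric function to one observer's trials.

    Raises on degenerate input (fewer than two velocity levels, or a
    constant response pattern, mirroring the at-chance exclusion rule).
    Complete separation is reported as a flagged fit with an infinite
    slope rather than a silently diverged estimate.
    """
    if "n" in trials.columns and "k" in trials.columns:
        counts = trials[["v_surf", "n", "k"]].copy() if velocity_col == "v_surf" else trials.rename(
            columns={velocity_col: "v_surf"}
        )[["v_surf", "n", "k"]]
    else:
        counts = aggregate_counts(trials, velocity_col)
    v = counts["v_surf"].to_numpy(dtype=float)
    n = counts["n"].to_numpy(dtype=float)
    k = counts["k"].to_numpy(dtype=float)
    if len(v) < 2:
        raise ValueError("need responses at >= 2 distinct velocity levels")
    if k.sum() == 0 or k.sum() == n.sum():
        raise ValueError("constant response probability: all responses identical")
    if _check_separation(v, k, n):
        sign = 1.0 if np.median(v[k > 0]) > np.median(v[k < n]) else -1.0
        return PsychometricFit(
            intercept=np.nan,
            slope=sign * np.inf,
            cov_params=np.full((2, 2), np.nan),
            loglik=0.0,
            n_trials=int(n.sum()),
            converged=False,
            separation=True,
        )
    X = sm.add_constant(v)
    model = sm.GLM(np.column_stack([k, n - k]), X, family=sm.families.Binomial(sm.families.links.Probit()))
    res = model.fit()
    return PsychometricFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        cov_params=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        n_trials=int(n.sum()),
        converged=bool(res.converged),
    )


def fit_discrimination(trials: pd.DataFrame) -> PsychometricFit:
    """Probit fit for two-interval speed discrimination.

    Expects ``v_surf`` to hold the signed speed difference between the
    comparison and the reference interval and ``response = 1`` when the
    comparison was judged faster.  The JND is read from the fitted slope;
    with a symmetric design the point of equality sits near zero.
    """
    return fit_probit_ml(trials)


def lrt_slopes(fit_full, fit_reduced) -> tuple[float, int, float]:
    """Likelihood-ratio test between two nested fits on the same data.

    Both arguments must expose ``loglik``, ``n_params`` and ``n_trials``.
    Returns ``(statistic, df, p_value)`` with the statistic floored at zero
    (optimiser jitter can leave it marginally negative for identical
    models).
    """
    if fit_full.n_trials != fit_reduced.n_trials:
        raise ValueError("LRT requires both models fitted to the same data")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("fit_full must have at least as many parameters as fit_reduced")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------------
# Vectorised Newton probit fitter on aggregated counts (bootstrap engine)


def batch_probit_counts(
    k: np.ndarray,
    n: np.ndarray,
    X: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-scoring probit MLE, vectorised over a batch of datasets.

    Parameters
    ----------
    k : array (B, L)
        Success counts per dataset and design cell.
    n : array (L,) or (B, L)
        Trial counts per cell.
    X : array (L, P)
        Shared design matrix.
    beta0 : array (P,) or (B, P), optional
        Starting values (defaults to zero).

    Returns
    -------
    beta : array (B, P), loglik : array (B,)
        ML estimates and Bernoulli log-likelihoods (including binomial
        coefficients, so values are comparable with statsmodels).
    """
    k = np.atleast_2d(np.asarray(k, dtype=float))
    B, L = k.shape
    n = np.broadcast_to(np.asarray(n, dtype=float), (B, L))
    P = X.shape[1]
    beta = np.zeros((B, P)) if beta0 is None else np.broadcast_to(np.asarray(beta0, float), (B, P)).copy()
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T, -8.0, 8.0)
        p = np.clip(norm.cdf(eta), _PCLIP, 1.0 - _PCLIP)
        pdf = norm.pdf(eta)
        resid = pdf * (k / p - (n - k) / (1.0 - p))  # (B, L)
        W = n * pdf**2 / (p * (1.0 - p))
        grad = resid @ X  # (B, P)
        info = np.einsum("bl,lp,lq->bpq", W, X, X)
        info += 1e-10 * np.eye(P)
        step = np.linalg.solve(info, grad[..., None])[..., 0]
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(beta @ X.T, -8.0, 8.0)
    p = np.clip(norm.cdf(eta), _PCLIP, 1.0 - _PCLIP)
    const = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    loglik = (const + k * np.log(p) + (n - k) * np.log(1.0 - p)).sum(axis=1)
    return beta, loglik


def bootstrap_probit_pse(
    b0: float,
    b1: float,
    velocities: Sequence[float],
    n_per_level: int,
    n_reps: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """Parametric-bootstrap percentile CI for the PSE of a probit fit.

    Simulates ``n_reps`` binomial datasets from the fitted probit response
    function, refits each, and returns the percentile 95% interval of the
    PSE replicates.  Replicates with a numerically degenerate slope are
    dropped and counted.
    """
    rng = np.random.default_rng(seed)
    v = np.asarray(velocities, dtype=float)
    p = norm.cdf(b0 + b1 * v)
    k = rng.binomial(n_per_level, p, size=(n_reps, len(v))).astype(float)
    X = np.column_stack([np.ones_like(v), v])
    beta, _ = batch_probit_counts(k, float(n_per_level), X, beta0=np.array([b0, b1]))
    ok = np.abs(beta[:, 1]) > 1e-8
    pse = -beta[ok, 0] / beta[ok, 1]
    lo, hi = np.percentile(pse, [2.5, 97.5])
    return BootstrapResult(
        estimate=-b0 / b1,
        replicates=pse,
        ci_low=float(lo),
        ci_high=float(hi),
        n_reps=n_reps,
        n_failed=int(n_reps - ok.sum()),
        seed=seed,
    )
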