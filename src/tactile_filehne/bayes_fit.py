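"""Maximum-likelihood fitting of the Bayesian observer to trial data.

The observer model has three parameters -- the stationarity-prior variance
and the two likelihood variances -- but the prior variance is only weakly
identified (a large change in the variances moves the shrinkage weights
very little when prior and likelihood variances are far apart), so it is
held fixed during fitting, as a constraint.  The model is scale-invariant
in the variances, so the constraint value sets the overall scale while the
proprioceptive/tactile variance ratio, which drives the illusion, is
insensitive to it.

The population-level procedure is a parametric bootstrap: binomial
responses are simulated per condition from descriptive probit fits, the
observer model is refit to each replicate, and percentile intervals are
taken over the replicate parameters and predicted PSEs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .observer import (
    ObserverParams,
    PsychometricParams,
    calibrate_prior_variance,
    predicted_psychometric,
)
from .synth import simulate_binomial_from_probit

__all__ = [
    "BayesFitResult",
    "BootstrapFitDistribution",
    "DEFAULT_PRIOR_VARIANCE",
    "fit_observer_model",
    "negloglik_observer_model",
    "parametric_bootstrap_fit",
]

logger = logging.getLogger(__name__)

_PCLIP = 1e-12

#: Default prior-variance constraint: the value at which the predicted
#: proprioceptive-only probit slope equals 0.02 for a likelihood variance
#: of 34 mm^2/s^2 (the unimodal calibration of the observer model).
DEFAULT_PRIOR_VARIANCE: float = calibrate_prior_variance(0.02, 34.0)

_MAIN_LIKE = ("main", "high_amp")


@dataclass
class BayesFitResult:
    """Constrained ML fit of the observer model."""

    sigma2_prop: float
    sigma2_tact: float
    sigma2_prior: float
    kappa_low_amp: float
    loglik: float
    converged: bool
    n_starts: int
    v_pursuit: float
    predicted: dict = field(default_factory=dict)
    message: str = ""

    @property
    def variance_ratio(self) -> float:
        """Proprioceptive-to-tactile likelihood-variance ratio."""
        return self.sigma2_prop / self.sigma2_tact

    @property
    def predicted_pse_main(self) -> float:
        return self.predicted["main"].pse if "main" in self.predicted else np.nan


def _cells_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    if {"n", "k"}.issubset(trials.columns):
        return trials[["condition", "v_surf", "n", "k"]].copy()
    g = trials.groupby(["condition", "v_surf"])["response"].agg(["count", "sum"]).reset_index()
    return g.rename(columns={"count": "n", "sum": "k"})


def _condition_psychometric(params: ObserverParams, condition: str) -> PsychometricParams:
    if condition in _MAIN_LIKE:
        return predicted_psychometric(params, "main")
    if condition == "low_amp":
        return predicted_psychometric(params.with_low_amplitude(), "main")
    if condition == "control":
        return predicted_psychometric(params, "control")
    raise ValueError(f"unknown condition {condition!r}")


def negloglik_observer_model(params: ObserverParams, trials: pd.DataFrame) -> float:
    """Negative Bernoulli log-likelihood of the observer model.

    Control-condition trials drop the proprioceptive channel; low-amplitude
    trials inflate the tactile variance by ``kappa_low_amp``.  Response
    probabilities are clamped at 1e-12 for numerical stability (clamping is
    logged at debug level).
    """
    cells = _cells_from_trials(trials)
    nll = 0.0
    for cond, grp in cells.groupby("condition"):
        psy = _condition_psychometric(params, str(cond))
        v = grp["v_surf"].to_numpy(dtype=float)
        n = grp["n"].to_numpy(dtype=float)
        k = grp["k"].to_numpy(dtype=float)
        p = norm.cdf(psy.intercept + psy.slope * v)
        clipped = (p < _PCLIP) | (p > 1 - _PCLIP)
        if clipped.any():
            logger.debug("clamped %d response probabilities in condition %s", int(clipped.sum()), cond)
        p = np.clip(p, _PCLIP, 1 - _PCLIP)
        nll -= float((k * np.log(p) + (n - k) * np.log1p(-p)).sum())
    return nll


def fit_observer_model(
    trials: pd.DataFrame,
    sigma2_prior: float = DEFAULT_PRIOR_VARIANCE,
    v_pursuit: float | None = None,
    fit_kappa: bool = False,
    start: Sequence[float] | None = None,
    log_bounds: tuple[float, float] = (-4.0, 10.0),
    n_starts: int = 5,
    seed: int = 0,
) -> BayesFitResult:
    """Constrained ML estimation of the likelihood variances.

    Optimises ``(sigma2_prop, sigma2_tact)`` (plus ``kappa_low_amp`` when
    amplitude conditions are present and ``fit_kappa`` is set) on the log
    scale with a derivative-free simplex search from ``n_starts`` starting
    points, keeping the prior variance fixed at ``sigma2_prior``.  The
    flat directions of the likelihood make multi-start a necessity rather
    than a luxury.
    """
    cells = _cells_from_trials(trials)
    conditions = sorted(cells["condition"].unique())
    if v_pursuit is None:
        if "v_prop" in trials.columns:
            moving = trials.loc[trials["v_prop"] != 0.0, "v_prop"]
            v_pursuit = float(moving.mean()) if len(moving) else 10.8
        else:
            v_pursuit = 10.8
    has_amplitude = "low_amp" in conditions
    fit_kappa = fit_kappa and has_amplitude

    def build(theta: np.ndarray) -> ObserverParams:
        kappa = float(np.exp(theta[2])) + 1.0 if fit_kappa else 2.0
        return ObserverParams.single_prior(
            sigma2_prior,
            float(np.exp(theta[0])),
            float(np.exp(theta[1])),
            v_pursuit=v_pursuit,
            kappa_low_amp=kappa,
        )

    # aggregate once; the optimiser evaluates on plain arrays
    grouped = [
        (
            str(cond),
            grp["v_surf"].to_numpy(dtype=float),
            grp["n"].to_numpy(dtype=float),
            grp["k"].to_numpy(dtype=float),
        )
        for cond, grp in cells.groupby("condition")
    ]

    def objective(theta: np.ndarray) -> float:
        if np.any(theta[:2] < log_bounds[0]) or np.any(theta[:2] > log_bounds[1]):
            return 1e10
        try:
            params = build(theta)
            nll = 0.0
            for cond, v, n, k in grouped:
                psy = _condition_psychometric(params, cond)
                p = np.clip(norm.cdf(psy.intercept + psy.slope * v), _PCLIP, 1 - _PCLIP)
                nll -= float((k * np.log(p) + (n - k) * np.log1p(-p)).sum())
            return nll
        except (ValueError, FloatingPointError):
            return 1e10

    rng = np.random.default_rng(seed)
    n_free = 3 if fit_kappa else 2
    starts = []
    if start is not None:
        starts.append(np.log(np.asarray(start, dtype=float)))
    base = np.log([30.0, 10.0, 1.0][:n_free])
    starts.append(base)
    while len(starts) < n_starts:
        starts.append(base + rng.uniform(-2.0, 2.0, size=n_free))
    best = None
    for theta0 in starts[:n_starts]:
        res = minimize(objective, theta0, method="Nelder-Mead", options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError("observer-model fit failed from all starting points")
    params = build(best.x)
    predicted = {c: _condition_psychometric(params, c) for c in conditions}
    return BayesFitResult(
        sigma2_prop=params.sigma2_prop,
        sigma2_tact=params.sigma2_tact,
        sigma2_prior=sigma2_prior,
        kappa_low_amp=params.kappa_low_amp if fit_kappa else (2.0 if has_amplitude else 1.0),
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_starts=n_starts,
        v_pursuit=v_pursuit,
        predicted=predicted,
        message=str(best.message),
    )


@dataclass
class BootstrapFitDistribution:
    """Replicate distribution of observer-model fits."""

    sigma2_prop: np.ndarray
    sigma2_tact: np.ndarray
    pse_main: np.ndarray
    n_reps: int
    n_failed: int
    seed: int | None

    def ci(self, which: str = "pse_main", level: float = 0.95) -> tuple[float, float]:
        arr = getattr(self, which)
        alpha = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(arr, [alpha, 100.0 - alpha])
        return float(lo), float(hi)


def parametric_bootstrap_fit(
    probit_params: Mapping[str, tuple[float, float]],
    design: Mapping[str, tuple[Sequence[float], int]],
    n_reps: int = 1000,
    seed: int | None = None,
    sigma2_prior: float = DEFAULT_PRIOR_VARIANCE,
    v_pursuit: float = 10.8,
    n_starts: int = 2,
) -> BootstrapFitDistribution:
    """Population-level parametric bootstrap of the observer-model fit.

    ``probit_params[cond] = (b0, b1)`` are the descriptive probit
    intercept/slope per condition (e.g. the hierarchical fixed effects);
    ``design[cond] = (velocity levels, trials per level)``.  Each replicate
    simulates per-level binomial counts, refits the constrained observer
    model, and records the variances and the predicted main-task PSE.
    """
    rng = np.random.default_rng(seed)
    s2p, s2t, pse = [], [], []
    failures = 0
    for _ in range(n_reps):
        frames = []
        for cond, (b0, b1) in probit_params.items():
            levels, n_per = design[cond]
            counts = simulate_binomial_from_probit(b0, b1, levels, n_per, int(rng.integers(2**31)))
            counts["condition"] = cond
            frames.append(counts)
        cells = pd.concat(frames, ignore_index=True)
        try:
            fit = fit_observer_model(
                cells,
                sigma2_prior=sigma2_prior,
                v_pursuit=v_pursuit,
                n_starts=n_starts,
                seed=int(rng.integers(2**31)),
            )
        except RuntimeError:
            failures += 1
            continue
        s2p.append(fit.sigma2_prop)
        s2t.append(fit.sigma2_tact)
        main_cond = next((c for c in fit.predicted if c in _MAIN_LIKE), None)
        pse.append(fit.predicted[main_cond].pse if main_cond else np.nan)
    return BootstrapFitDistribution(
        sigma2_prop=np.asarray(s2p),
        sigma2_tact=np.asarray(s2t),
        pse_main=np.asarray(pse),
        n_reps=n_reps,
        n_failed=failures,
        seed=seed,
    )
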