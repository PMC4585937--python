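"""Synthetic experiments: designs, observer populations, binary responses.

Three experiment layouts are emulated:

* ``exp1`` -- direction judgements with a moving (main) or stationary
  (control) finger; 105 main trials over seven velocities including zero
  and 90 control trials over six nonzero velocities.
* ``exp2`` -- the main-task geometry with the pin oscillation amplitude
  randomly intermixed between 0.1 mm (high) and 0.04 mm (low) over a single
  200-trial block, which modulates tactile measurement noise.
* ``exp3`` -- two-interval speed discrimination with a stationary hand, at
  the same two amplitudes.

Responses can be generated either from the Bayesian observer model
(:func:`simulate_observer_responses`) or from a hierarchical probit
population with bivariate-Gaussian random intercepts and slopes
(:func:`simulate_population`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .observer import (
    ObserverParams,
    predicted_psychometric,
    predicted_unimodal_slope,
)

__all__ = [
    "CANONICAL_COLUMNS",
    "PopulationSpec",
    "make_design",
    "population_from_observer",
    "simulate_binomial_from_probit",
    "simulate_observer_responses",
    "simulate_population",
]

#: Canonical column order of a trial table.
CANONICAL_COLUMNS = [
    "observer_id",
    "experiment",
    "condition",
    "v_surf",
    "v_prop",
    "amplitude",
    "response",
]

HIGH_AMPLITUDE = 0.1  # mm
LOW_AMPLITUDE = 0.04  # mm

EXP1_MAIN_VELOCITIES = (-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0)
EXP1_CONTROL_VELOCITIES = (-30.0, -20.0, -10.0, 10.0, 20.0, 30.0)
EXP2_VELOCITIES = (-20.0, -10.0, 0.0, 10.0, 20.0)
EXP3_DELTAS = (-12.0, -8.0, -4.0, 0.0, 4.0, 8.0, 12.0)
EXP3_REFERENCE_SPEED = 30.0  # mm/s


@dataclass
class PopulationSpec:
    """Hierarchical-probit generative population.

    Each observer draws a random intercept/slope pair from a bivariate
    Gaussian with covariance ``re_cov`` which is added to the per-condition
    fixed effects ``(intercept, slope)``.
    """

    n_observers: int
    fixed_effects: Mapping[str, tuple[float, float]]
    re_cov: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def __post_init__(self) -> None:
        self.re_cov = np.asarray(self.re_cov, dtype=float)
        if self.re_cov.shape != (2, 2):
            raise ValueError("re_cov must be 2x2")
        if not np.allclose(self.re_cov, self.re_cov.T):
            raise ValueError("re_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.re_cov) < -1e-12):
            raise ValueError("re_cov must be positive semidefinite")
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")


def make_design(
    experiment: str,
    seed: int | None = None,
    *,
    pursuit_speed: float = 10.8,
    main_velocities: Sequence[float] = EXP1_MAIN_VELOCITIES,
    control_velocities: Sequence[float] = EXP1_CONTROL_VELOCITIES,
    reps_per_level: int = 15,
    exp2_velocities: Sequence[float] = EXP2_VELOCITIES,
    exp2_reps: int = 20,
    exp3_deltas: Sequence[float] = EXP3_DELTAS,
    exp3_reps: int = 15,
) -> pd.DataFrame:
    """Stimulus table (no responses) for one experimental session.

    Velocity levels and repetition counts are overridable; the defaults
    factor the session sizes of the three experiments (7x15 = 105 main plus
    6x15 = 90 control trials for exp1; 5 velocities x 2 amplitudes x 20
    repetitions = 200 trials for exp2).  Passing a seed shuffles the trial
    order reproducibly; ``None`` leaves the design in factorial order.
    """
    if experiment == "exp1":
        rows = [
            ("main", v, pursuit_speed, HIGH_AMPLITUDE)
            for v in main_velocities
            for _ in range(reps_per_level)
        ] + [
            ("control", v, 0.0, HIGH_AMPLITUDE)
            for v in control_velocities
            for _ in range(reps_per_level)
        ]
        design = pd.DataFrame(rows, columns=["condition", "v_surf", "v_prop", "amplitude"])
    elif experiment == "exp2":
        rows = [
            (cond, v, pursuit_speed, amp)
            for cond, amp in (("high_amp", HIGH_AMPLITUDE), ("low_amp", LOW_AMPLITUDE))
            for v in exp2_velocities
            for _ in range(exp2_reps)
        ]
        design = pd.DataFrame(rows, columns=["condition", "v_surf", "v_prop", "amplitude"])
    elif experiment == "exp3":
        rows = [
            (cond, d, 0.0, amp)
            for cond, amp in (("high_amp", HIGH_AMPLITUDE), ("low_amp", LOW_AMPLITUDE))
            for d in exp3_deltas
            for _ in range(exp3_reps)
        ]
        design = pd.DataFrame(rows, columns=["condition", "v_surf", "v_prop", "amplitude"])
        design["v_std"] = EXP3_REFERENCE_SPEED
        design["v_cmp"] = EXP3_REFERENCE_SPEED + design["v_surf"]
    else:
        raise ValueError(f"unknown experiment {experiment!r}; expected 'exp1', 'exp2' or 'exp3'")
    design.insert(0, "experiment", experiment)
    if seed is not None:
        rng = np.random.default_rng(seed)
        design = design.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    return design


def _condition_probability(params: ObserverParams, condition: str, v_surf: np.ndarray) -> np.ndarray:
    """Away-response (or faster-comparison) probability per trial."""
    if condition == "main":
        psy = predicted_psychometric(params, "main")
    elif condition == "control":
        psy = predicted_psychometric(params, "control")
    elif condition == "high_amp":
        psy = predicted_psychometric(params, "main")
    elif condition == "low_amp":
        psy = predicted_psychometric(params.with_low_amplitude(), "main")
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return norm.cdf(psy.intercept + psy.slope * v_surf)


def _discrimination_probability(params: ObserverParams, condition: str, delta: np.ndarray) -> np.ndarray:
    # Each interval's perceived speed is one tactile posterior draw; the
    # response indicates the larger draw, so the probit slope on the speed
    # difference is the unimodal tactile slope divided by sqrt(2).
    p = params.with_low_amplitude() if condition == "low_amp" else params
    slope = predicted_unimodal_slope(p.sigma2_prior_tact, p.sigma2_tact) / np.sqrt(2.0)
    return norm.cdf(slope * delta)


def simulate_observer_responses(
    params: ObserverParams,
    design: pd.DataFrame,
    seed: int,
    observer_id: str = "o01",
) -> pd.DataFrame:
    """Bernoulli responses of one Bayesian observer on a design table.

    The hit probability of every trial is the closed-form away-response
    probability of the observer model (condition labels select the task
    geometry; low-amplitude trials inflate the tactile variance by
    ``kappa_low_amp``).  Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    design = design.reset_index(drop=True)
    p = np.empty(len(design))
    experiment = design["experiment"].iloc[0] if len(design) else "exp1"
    for cond, idx in design.groupby("condition").groups.items():
        v = design.loc[idx, "v_surf"].to_numpy(dtype=float)
        if experiment == "exp3":
            p[idx] = _discrimination_probability(params, str(cond), v)
        else:
            p[idx] = _condition_probability(params, str(cond), v)
    out = design.copy()
    out.insert(0, "observer_id", observer_id)
    out["response"] = (rng.random(len(out)) < p).astype(int)
    return out


def simulate_population(spec: PopulationSpec, design: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Trial table for a heterogeneous hierarchical-probit population.

    For observer ``i`` a pair ``(u0, u1)`` is drawn from N(0, re_cov) and
    the away probability on a trial with velocity ``v`` in condition ``c``
    is ``Phi((theta0_c + u0) + (theta1_c + u1) v)``.  The random pair is
    shared across conditions within an observer.
    """
    try:
        chol = np.linalg.cholesky(spec.re_cov + 1e-15 * np.eye(2))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by __post_init__
        raise ValueError("re_cov must be positive semidefinite") from exc
    rng = np.random.default_rng(seed)
    missing = set(design["condition"]) - set(spec.fixed_effects)
    if missing:
        raise ValueError(f"fixed_effects missing conditions: {sorted(missing)}")
    frames = []
    width = max(2, len(str(spec.n_observers)))
    for i in range(spec.n_observers):
        u = chol @ rng.standard_normal(2)
        obs = design.copy().reset_index(drop=True)
        theta0 = obs["condition"].map(lambda c: spec.fixed_effects[c][0]).to_numpy()
        theta1 = obs["condition"].map(lambda c: spec.fixed_effects[c][1]).to_numpy()
        eta = (theta0 + u[0]) + (theta1 + u[1]) * obs["v_surf"].to_numpy(dtype=float)
        obs.insert(0, "observer_id", f"o{i + 1:0{width}d}")
        obs["response"] = (rng.random(len(obs)) < norm.cdf(eta)).astype(int)
        frames.append(obs)
    return pd.concat(frames, ignore_index=True)


def population_from_observer(
    params: ObserverParams,
    conditions: Sequence[str],
    re_cov: np.ndarray,
    n_observers: int,
) -> PopulationSpec:
    """Population whose fixed effects are the observer-model predictions."""
    fixed: dict[str, tuple[float, float]] = {}
    for cond in conditions:
        if cond == "low_amp":
            psy = predicted_psychometric(params.with_low_amplitude(), "main")
        elif cond == "high_amp":
            psy = predicted_psychometric(params, "main")
        else:
            psy = predicted_psychometric(params, cond)
        fixed[cond] = (psy.intercept, psy.slope)
    return PopulationSpec(n_observers=n_observers, fixed_effects=fixed, re_cov=np.asarray(re_cov))


def simulate_binomial_from_probit(
    b0: float,
    b1: float,
    velocities: Sequence[float],
    n_per_level: int,
    seed: int,
) -> pd.DataFrame:
    """Per-level binomial counts from a probit response function.

    Draws ``k ~ Binomial(n, Phi(b0 + b1 v))`` at each velocity level; this
    is the simulation step of the parametric bootstrap.
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    v = np.asarray(velocities, dtype=float)
    p = norm.cdf(b0 + b1 * v)
    k = rng.binomial(n_per_level, p)
    return pd.DataFrame({"v_surf": v, "n": n_per_level, "k": k})
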