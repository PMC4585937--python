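"""Closed-form Bayesian observer with a stationarity prior.

The observer estimates the world-centred velocity of a surface explored with
a moving finger.  Two sensory channels contribute: proprioception reports the
finger (pursuit) velocity ``v_prop`` and cutaneous touch reports the relative
slip velocity ``v_tact = v_surf - v_prop``.  Each noisy measurement is fused
with a zero-mean Gaussian prior over velocity ("objects are usually at
rest"), which shrinks the channel estimate toward zero by the weight

    w = sigma2_prior / (sigma2_prior + sigma2_likelihood).

Because proprioception is noisier than touch, the proprioceptive estimate is
shrunk more, and the sum of the two posterior samples is biased: a
world-stationary surface is perceived as moving opposite to the hand -- the
tactile analogue of the Filehne illusion.

All velocities are in mm/s with away-from-the-body positive; variances are
in mm^2/s^2.  Probit slopes are in probit units per mm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.stats import norm

__all__ = [
    "Z75",
    "ChannelPosterior",
    "FusedEstimate",
    "ObserverParams",
    "PsychometricParams",
    "calibrate_prior_variance",
    "filehne_gain",
    "fused_distribution",
    "jnd_from_slope",
    "perceived_velocity_biased",
    "predicted_psychometric",
    "predicted_unimodal_slope",
    "response_probability",
    "shrinkage_weight",
]

#: 75%-criterion quantile used to convert a probit slope into a JND.
Z75: float = float(norm.ppf(0.75))


@dataclass(frozen=True)
class ChannelPosterior:
    """Posterior of one sensory channel after fusion with the static prior.

    ``weight`` is the shrinkage factor applied to the measurement (the
    posterior mean given measurement ``m`` is ``weight * m``); ``post_var``
    is the posterior variance ``weight * sigma2_likelihood``.
    """

    weight: float
    post_var: float


@dataclass(frozen=True)
class FusedEstimate:
    """Gaussian distribution of the fused surface-velocity estimate."""

    mean: float
    sd: float


@dataclass(frozen=True)
class PsychometricParams:
    """Probit psychometric function predicted by the observer model."""

    intercept: float
    slope: float
    pse: float
    jnd: float


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the Bayesian observer.

    Parameters
    ----------
    sigma2_prior_prop, sigma2_prior_tact
        Variances of the zero-mean stationarity priors applied to the
        initial-velocity (proprioceptive) and velocity-change (tactile)
        estimates.  Equal values recover the single-prior model.
    sigma2_prop, sigma2_tact
        Likelihood (measurement-noise) variances of the two channels.
    v_pursuit
        Mean pursuit velocity of the finger in the moving-hand task.
    kappa_low_amp
        Multiplicative factor (>= 1) applied to ``sigma2_tact`` when the pin
        oscillation amplitude is reduced (low tactile contrast).
    """

    sigma2_prior_prop: float
    sigma2_prior_tact: float
    sigma2_prop: float
    sigma2_tact: float
    v_pursuit: float = 10.8
    kappa_low_amp: float = 2.0

    def __post_init__(self) -> None:
        for name in ("sigma2_prior_prop", "sigma2_prior_tact", "sigma2_prop", "sigma2_tact"):
            value = getattr(self, name)
            if not (value > 0.0 and math.isfinite(value)):
                raise ValueError(f"{name} must be a positive finite variance, got {value!r}")
        if not self.kappa_low_amp >= 1.0:
            raise ValueError(f"kappa_low_amp must be >= 1, got {self.kappa_low_amp!r}")
        if not math.isfinite(self.v_pursuit):
            raise ValueError("v_pursuit must be finite")

    @classmethod
    def single_prior(
        cls,
        sigma2_prior: float,
        sigma2_prop: float,
        sigma2_tact: float,
        v_pursuit: float = 10.8,
        kappa_low_amp: float = 2.0,
    ) -> "ObserverParams":
        """Observer with one common stationarity prior for both channels."""
        return cls(sigma2_prior, sigma2_prior, sigma2_prop, sigma2_tact, v_pursuit, kappa_low_amp)

    @property
    def is_single_prior(self) -> bool:
        return self.sigma2_prior_prop == self.sigma2_prior_tact

    def with_low_amplitude(self) -> "ObserverParams":
        """Parameters for the low pin-amplitude (noisier touch) condition."""
        return replace(self, sigma2_tact=self.sigma2_tact * self.kappa_low_amp, kappa_low_amp=1.0)


def shrinkage_weight(sigma2_prior: float, sigma2_like: float) -> ChannelPosterior:
    """Conjugate-Gaussian posterior of one channel.

    With prior N(0, sigma2_prior) and likelihood N(v, sigma2_like), the
    posterior given measurement ``m`` is N(w*m, w*sigma2_like) with
    ``w = sigma2_prior / (sigma2_prior + sigma2_like)``.  A noisier channel
    (larger ``sigma2_like``) is pulled harder toward the stationary prior.
    """
    if not sigma2_prior > 0.0:
        raise ValueError(f"sigma2_prior must be > 0, got {sigma2_prior!r}")
    if not sigma2_like > 0.0:
        raise ValueError(f"sigma2_like must be > 0, got {sigma2_like!r}")
    w = sigma2_prior / (sigma2_prior + sigma2_like)
    return ChannelPosterior(weight=w, post_var=w * sigma2_like)


def fused_distribution(
    params: ObserverParams,
    v_surf: float,
    v_prop: float | None = None,
    proprioception_active: bool = True,
) -> FusedEstimate:
    """Distribution of the fused surface-velocity estimate on one trial.

    The estimate is the sum of one random sample from each channel
    posterior, where each posterior is itself centred on a noisy
    measurement.  Marginalising over the measurement noise, each channel
    contributes mean ``w * v_channel`` and variance ``w^2 * sigma2_like +
    post_var`` (propagated measurement noise plus posterior-sampling
    variance).

    When ``proprioception_active`` is False (stationary finger) the
    proprioceptive channel is discarded entirely and the slip velocity
    equals the surface velocity.
    """
    if v_prop is None:
        v_prop = params.v_pursuit
    tact = shrinkage_weight(params.sigma2_prior_tact, params.sigma2_tact)
    if proprioception_active:
        prop = shrinkage_weight(params.sigma2_prior_prop, params.sigma2_prop)
        dv = v_surf - v_prop
        mean = prop.weight * v_prop + tact.weight * dv
        var = (
            prop.weight**2 * params.sigma2_prop
            + tact.weight**2 * params.sigma2_tact
            + prop.post_var
            + tact.post_var
        )
    else:
        mean = tact.weight * v_surf
        var = tact.weight**2 * params.sigma2_tact + tact.post_var
    return FusedEstimate(mean=mean, sd=math.sqrt(var))


def response_probability(
    params: ObserverParams,
    v_surf: float,
    v_prop: float | None = None,
    proprioception_active: bool = True,
) -> float:
    """Probability of an "away" response, P(fused estimate > 0)."""
    fused = fused_distribution(params, v_surf, v_prop, proprioception_active)
    return float(norm.cdf(fused.mean / fused.sd))


def predicted_psychometric(params: ObserverParams, condition: str) -> PsychometricParams:
    """Probit psychometric function predicted for one task condition.

    ``condition`` is ``"main"`` (moving finger; proprioception active with
    ``v_prop = v_pursuit``) or ``"control"`` (stationary finger;
    proprioception discarded).  The away-response probability is linear on
    the probit scale:

        probit P(away) = intercept + slope * v_surf

    with ``slope = w_tact / sd`` and, in the main task,
    ``intercept = (w_prop - w_tact) * v_prop / sd``, giving

        PSE_main = v_prop * (1 - w_prop / w_tact),    PSE_control = 0.

    A main condition with zero pursuit velocity degenerates to the control
    geometry and is routed there.
    """
    if condition not in ("main", "control"):
        raise ValueError(f"unknown condition {condition!r}; expected 'main' or 'control'")
    active = condition == "main" and params.v_pursuit != 0.0
    tact = shrinkage_weight(params.sigma2_prior_tact, params.sigma2_tact)
    if active:
        prop = shrinkage_weight(params.sigma2_prior_prop, params.sigma2_prop)
        sd = fused_distribution(params, 0.0, params.v_pursuit, True).sd
        slope = tact.weight / sd
        intercept = (prop.weight - tact.weight) * params.v_pursuit / sd
        pse = params.v_pursuit * (1.0 - prop.weight / tact.weight)
    else:
        sd = fused_distribution(params, 0.0, None, False).sd
        slope = tact.weight / sd
        intercept = 0.0
        pse = 0.0
    return PsychometricParams(intercept=intercept, slope=slope, pse=pse, jnd=jnd_from_slope(slope))


def predicted_unimodal_slope(sigma2_prior: float, sigma2_like: float) -> float:
    """Probit slope of a simulated single-channel discrimination task.

    With the other channel discarded, the judged quantity is one posterior
    sample, distributed N(w*v, w^2*sigma2 + w*sigma2), hence

        slope = w / sqrt(w^2 sigma2 + w sigma2) = sqrt(w / (sigma2 (1 + w))).
    """
    post = shrinkage_weight(sigma2_prior, sigma2_like)
    w = post.weight
    return math.sqrt(w / (sigma2_like * (1.0 + w)))


def calibrate_prior_variance(slope_target: float, sigma2_like: float) -> float:
    """Prior variance that yields a given unimodal probit slope.

    Inverts :func:`predicted_unimodal_slope` in closed form:
    ``w = s^2 sigma2 / (1 - s^2 sigma2)`` and then
    ``sigma2_prior = w sigma2 / (1 - w)``.  The slope is attainable only
    for ``0 < slope_target < 1/sqrt(2 sigma2)``, the ``w -> 1`` limit of an
    infinitely wide (non-shrinking) prior.
    """
    if not sigma2_like > 0.0:
        raise ValueError(f"sigma2_like must be > 0, got {sigma2_like!r}")
    s2v = slope_target**2 * sigma2_like
    if not (slope_target > 0.0 and s2v < 0.5):
        upper = 1.0 / math.sqrt(2.0 * sigma2_like)
        raise ValueError(
            f"slope_target {slope_target!r} outside the attainable range (0, {upper:.6g}) "
            f"for likelihood variance {sigma2_like!r}"
        )
    w = s2v / (1.0 - s2v)
    return w * sigma2_like / (1.0 - w)


def jnd_from_slope(slope: float) -> float:
    """Just-noticeable difference (75% criterion) from a probit slope."""
    if not slope > 0.0:
        raise ValueError(f"slope must be > 0, got {slope!r}")
    return Z75 / slope


def filehne_gain(pse_main: float, v_pursuit_mean: float) -> float:
    """Haptic Filehne gain, ``1 - PSE_main / mean pursuit velocity``.

    Gain 1 means veridical compensation for the moving finger (no surface
    motion is needed to null the percept, PSE = 0); gain 0 means no
    compensation at all (the surface must move with the finger, PSE equal
    to the pursuit velocity, to appear stationary).
    """
    if v_pursuit_mean == 0.0:
        raise ValueError("mean pursuit velocity must be nonzero")
    return 1.0 - pse_main / v_pursuit_mean


def perceived_velocity_biased(v_tact: float, v_prop: float, gain: float) -> float:
    """Perceived surface velocity of a biased observer.

    ``v_tact + gain * v_prop``; with ``gain = 1`` this is the ideal
    world-centred summation ``v_surf = v_tact + v_prop``.  For a stationary
    surface (``v_tact = -v_prop``) and gain < 1 the output is negative:
    the surface appears to move opposite to the hand.
    """
    return v_tact + gain * v_prop
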