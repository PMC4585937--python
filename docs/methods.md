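# Methods

## Observer model

The observer estimates the world-centred velocity of a surface explored
with the fingertip. Two Gaussian channels contribute:

* proprioception measures the finger (pursuit) velocity,
  `m_prop ~ N(v_prop, σ²_prop)`;
* cutaneous touch measures the slip on the skin,
  `m_tact ~ N(v_surf − v_prop, σ²_tact)` (with the hand stationary the
  slip equals the surface velocity).

Each measurement is fused with a zero-mean Gaussian stationarity prior.
For prior variance `σ²_S` the posterior given measurement `m` is
`N(w·m, w·σ²)` with shrinkage weight `w = σ²_S/(σ²_S+σ²)`. The fused
surface-velocity estimate is the **sum of one random sample from each
channel posterior**. Marginalising over the measurement noise, each
channel contributes mean `w·v` and variance `w²σ² + wσ²` — propagated
measurement noise plus posterior-sampling variance. This two-part
variance is a deliberate design choice: it is the only decomposition under
which one calibration of the prior variance simultaneously reproduces the
reference proprioceptive slope (0.02), the tactile slope (0.06) and the
main-task PSE (7.2 mm/s), so it is adopted as the reference formulation.

The response on a trial is "away" when the fused estimate is positive,
which makes the away-probability exactly probit-linear in `v_surf`:

* main task: `slope = w_t/σ_fused`, `PSE = v_prop(1 − w_p/w_t)`;
* control task (proprioception discarded, per the stationary-finger
  assumption): `slope = w_t/σ_ctrl`, `PSE = 0` structurally;
* unimodal (single-channel) discrimination:
  `slope = sqrt(w/(σ²(1+w)))`, inverted in closed form by
  `calibrate_prior_variance`.

Model structure worth noting:

* **Scale invariance.** Multiplying all variances by `c` leaves all
  weights and PSEs unchanged and divides all slopes by `√c`. This is why
  the prior variance is not identifiable from binary responses alone and
  is fixed (constrained) during fitting; only the variance *ratio*
  matters for the bias, and the fitted ratio is insensitive to the
  constraint (verified in the tests).
* **Two-prior variant.** `ObserverParams` carries separate prior
  variances for the initial-velocity and velocity-change estimates; equal
  values (the default) recover the single-prior model.
* **Degenerate geometry.** A "main" condition with zero pursuit velocity
  is routed to the control formulation.

The attainable-slope bound in `calibrate_prior_variance` is
`0 < s < 1/sqrt(2σ²)`: as the prior widens (`w → 1`) the unimodal slope
saturates at `1/sqrt(2σ²)`, not `1/sqrt(σ²)`, because the posterior-
sampling variance never vanishes.

## Parameters and defaults

| parameter | unit | default | rationale |
|---|---|---|---|
| `sigma2_prop` | mm²/s² | 34 | reference proprioceptive likelihood variance |
| `sigma2_tact` | mm²/s² | 11 | reference tactile likelihood variance |
| `sigma2_prior` | mm²/s² | 0.4753 | solved from the proprioceptive slope 0.02 at variance 34 |
| `v_pursuit` | mm/s | 10.8 | mean realised finger velocity for a commanded 10 mm/s |
| `kappa_low_amp` | — | 2.0 | low-amplitude tactile-variance inflation; a ×1.4 SD factor maps the ~1.4 ratio of the two discrimination JNDs (8.3/5.9) in the near-linear regime |

## Stimulus timeline

The pin array is modelled as 8 rows at 1.6 mm pitch with a 1.6 mm wrap
gap (spatial ridge period 12.8 mm), refreshed every 1.5 ms. The virtual
ridge position integrates the commanded slip velocity at the refresh
rate; the active row is the one whose one-pitch slot the ridge overlaps,
with the wrap gap absorbed into the last slot so that exactly one row is
active at all times and hand-offs are immediate. The 20 Hz/0.1 mm (or
0.04 mm) pin oscillation is carried as metadata only — downstream it
matters solely through the amplitude→noise mapping `kappa_low_amp` —
because no waveform-level quantity is consumed by the analysis. The row
pitch is inferred from the printed first-to-last-row relation
(12.8 = 7×1.6 + 1.6) and is configurable. Phase-2 velocity changes are
instantaneous.

## Synthetic experiments

The generator emulates the three session layouts:

* **exp1** — 105 moving-hand trials over seven velocities
  {−30…30 incl. 0} × 15 and 90 stationary-hand trials over the six
  nonzero velocities × 15. Exact level sets and repetition counts are
  not dictated by the session totals alone; the defaults are the natural
  factorisation (7×15, 6×15) and are overridable.
* **exp2** — 200 moving-hand trials with pin amplitude randomly
  intermixed: 5 velocities {−20…20} × 2 amplitudes × 20. The allocation
  across velocities/amplitudes is a package choice (only the total and
  the intermixing are constrained).
* **exp3** — two-interval speed discrimination at a 30 mm/s reference
  with signed differences {−12…12} × 2 amplitudes × 15, hand stationary.
  Each interval's perceived speed is one tactile posterior draw and the
  response indicates the larger draw, so the probit slope on the speed
  difference is the unimodal tactile slope divided by √2.

Responses come either from the observer model (Bernoulli at the
closed-form probability) or from a hierarchical probit population:
per-observer intercept/slope pairs drawn from a bivariate Gaussian around
condition-specific fixed effects. The default heterogeneity
(intercept SD 0.2, slope SD 0.015, uncorrelated) produces a
between-observer PSE spread of roughly ±4–5 mm/s around the group value,
matching the spread visible across individual observers in this kind of
task. All randomness flows through explicit seeds.

What the generator deliberately does **not** emulate: finger-tracking
error (pursuit is treated as accurate), reaction times, trial-order or
learning effects, lapses/guessing, and any speed dependence of the
likelihood variances (a constant-variance approximation over the ±30 mm/s
range). Passing recovery tests therefore shows that the estimators are
correct for data satisfying the model's own assumptions — not that real
tactile data satisfy them.

## Fitting

* **Per-observer probit** fits use statsmodels GLM (binomial, probit
  link) on aggregated counts; PSE/JND standard errors by the delta
  method. Degenerate inputs are surfaced, not silently fitted: constant
  response patterns raise (mirroring the at-chance exclusion rule), and
  complete separation returns a flagged fit with an infinite-slope
  indicator.
* **Hierarchical probit**: marginal maximum likelihood with a shared
  bivariate-Gaussian random intercept/slope per observer and
  condition-specific fixed effects (`equal_slopes=True` gives the nested
  reduced model for the slope LRT). The random effects are integrated by
  adaptive Gauss–Hermite quadrature — a tensor grid (7 nodes/dimension by
  default) re-centred at each observer's posterior mode and re-scaled by
  the Fisher information there; 1 node recovers the Laplace
  approximation. The quadrature was validated against dense 2-D grid
  integration. The covariance is parameterised by its log-Cholesky
  factors (bounded in log-space, so a boundary fit appears as a tiny
  rather than singular variance), and optimisation is Nelder–Mead from
  pooled-probit starting values. Posterior modes are cached between
  likelihood evaluations.
* **Bootstrap inference** is parametric throughout, with percentile
  intervals (the reported intervals in this literature are
  percentile-style; BCa is out of scope): simulate from the fitted
  model, refit (warm-started at the original estimate with loosened
  tolerances), collect PSEs and their difference; failed replicates are
  excluded and counted. A vectorised Fisher-scoring probit fitter backs
  the probit-level bootstrap so that thousands of refits cost
  milliseconds.
* **Observer-model fit**: the prior variance is constrained (default:
  the calibrated 0.475 mm²/s²) and the two likelihood variances are
  optimised on the log scale by Nelder–Mead from five starting points —
  the likelihood has flat directions (notably σ²_prop), so multi-start is
  load-bearing. Response probabilities are clamped at 1e-12; clamp events
  are logged. The population-level procedure simulates per-level binomial
  counts from descriptive probit parameters, refits the model per
  replicate, and takes percentile intervals of the parameters and the
  predicted main-task PSE.

## Problem sizes and tolerances

The test suite runs everything at the study's own scale or below: Monte-
Carlo oracle checks use 1e5–1e6 draws with 3-SE criteria (allowing the
statistically expected number of exceedances across 100 parameter sets);
recovery tests use 10 observers × 195 trials with bootstrap intervals at
40–60 replicates; coverage of the bootstrap PSE-difference interval is
measured over 200 outer replications at the probit level, where the
vectorised fitter makes the nested resampling cheap; LRT type-I
calibration uses 500 simulations. Production defaults are higher
(1000 bootstrap replicates, as in the analysis the package models).

## Known limitations

* The hierarchical bootstrap refits a full mixed model per replicate
  (~0.3 s at 10 × 195); thousand-replicate runs take minutes.
* No lapse-rate parameter; extreme-velocity misresponses would bias
  slopes in real data.
* The amplitude→noise mapping is a single multiplicative variance factor;
  no functional form linking pin amplitude to tactile SNR is modelled.
* Standard errors for the hierarchical fixed effects are provided via the
  bootstrap only (no analytic Hessian of the marginal likelihood).
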