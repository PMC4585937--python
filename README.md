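# tactile-filehne

Bayesian observer modelling and psychophysical analysis of the **tactile
Filehne illusion**: when a fingertip pursues a moving surface, a
world-stationary surface is perceived as drifting opposite to the hand —
the haptic counterpart of the visual illusion seen during smooth-pursuit
eye movements.

The package is aimed at computational psychophysicists who want to
simulate, fit and stress-test this class of stationarity-prior models on
two-alternative direction judgements, without needing behavioural data: a
first-class synthetic-data generator emulates the three experimental tasks
(moving-hand vs stationary-hand direction judgements, pin-amplitude
manipulation of tactile noise, and two-interval speed discrimination).

## The model

An observer judges the world-centred surface velocity `v_surf` from two
noisy channels: proprioception reports the finger velocity
`v_prop ~ N(v_prop, σ²_prop)` and cutaneous touch reports the slip
`v_tact = v_surf − v_prop ~ N(·, σ²_tact)`. Each measurement is combined
with a zero-mean Gaussian *stationarity prior* `S ~ N(0, σ²_S)`, which
shrinks the channel estimate by

    w = σ²_S / (σ²_S + σ²_likelihood),

and the surface-velocity estimate is the sum of one sample from each
channel posterior. Because proprioception is noisier, it is shrunk harder
(`w_prop < w_tact`), and the sum is biased: the predicted probit
psychometric function of the moving-hand task has

    PSE_main = v_prop · (1 − w_prop / w_tact)  >  0,

while the stationary-hand (control) task, where proprioception is
discarded, is predicted unbiased (`PSE = 0`). The strength of the illusion
is summarised by the *haptic Filehne gain* `1 − PSE_main / v̄_prop`
(1 = veridical compensation, 0 = none).

With the prior variance calibrated so that the proprioceptive-only probit
slope is 0.02 (at σ²_prop = 34 mm²/s²), the closed forms give a tactile
slope of 0.06 (at σ²_tact = 11 mm²/s²), JNDs of 33.7 and 11.2 mm/s, and a
main-task PSE of 7.2 mm/s at a 10.8 mm/s pursuit — one calibration, three
independent predictions.

The analysis side mirrors standard psychophysical practice: per-observer
probit fits, a hierarchical (mixed-effects) probit across observers with a
bivariate-Gaussian random intercept/slope (adaptive Gauss–Hermite
marginal likelihood), parametric-bootstrap percentile CIs for PSEs and
their differences, likelihood-ratio tests on slopes, and constrained
maximum-likelihood fitting of the observer model itself.

## Worked example

```python
from tactile_filehne.pipeline import RunConfig, run_pipeline

config = RunConfig(seed=7, n_observers=10,
                   bootstrap_reps=100, bayes_bootstrap_reps=100)
report = run_pipeline(config)
```

This simulates ten observers × 195 trials from the calibrated generative
observer (σ²_S = 0.475, σ²_prop = 34, σ²_tact = 11 mm²/s², pursuit
10.8 mm/s) with between-observer heterogeneity, then runs the full
analysis. One run printed:

```
PSE main     8.84   95% CI [6.76, 11.07]     mm/s
PSE control  1.23   95% CI [-0.99, 2.97]     mm/s
PSE difference (control − main)  -7.61  CI [-11.11, -4.78]  -> significant
Bayes fit    σ²_prop 57.2, σ²_tact 12.2  (ratio 4.7)
             predicted PSE: main 8.43, control 0.0
```

Read: the moving-hand task shows a strong positive bias (the illusion) —
a stationary surface needs to move ~9 mm/s away to feel stationary — while
the stationary-hand task is unbiased within its CI; the difference
interval excludes zero. The constrained observer-model fit attributes
this to proprioception being several times noisier than touch, and its
predicted control-task PSE is structurally zero. Estimates scatter around
the generative truths (PSE 7.2 / 0.0, variances 34 / 11) with the sampling
noise expected at this study size; the proprioceptive variance is the
flattest direction of the likelihood and correspondingly the most
variable.

The same stages are available as CLI subcommands
(`tactile-filehne simulate | fit-psychometric | fit-bayes | bootstrap |
report`).

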