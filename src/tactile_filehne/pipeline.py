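"""End-to-end analysis pipeline and run configuration.

A run simulates (or loads) a trial table, fits per-observer probits, the
hierarchical probit with bootstrap PSE intervals, and the constrained
Bayesian observer model with its population bootstrap, then summarises the
haptic Filehne gain and JNDs in a single JSON-serialisable report.  A run
is reproducible from the configuration and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes_fit, hierarchical, psychometrics, synth
from .observer import ObserverParams, filehne_gain
from .io import read_trials, write_trials

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Complete, serialisable description of a pipeline run."""

    experiment: str = "exp1"
    seed: int = 0
    n_observers: int = 10
    # generative observer (single prior, calibrated constraint by default)
    sigma2_prior: float = bayes_fit.DEFAULT_PRIOR_VARIANCE
    sigma2_prop: float = 34.0
    sigma2_tact: float = 11.0
    v_pursuit: float = 10.8
    kappa_low_amp: float = 2.0
    # between-observer heterogeneity (random intercept/slope variances)
    re_var_intercept: float = 0.04
    re_var_slope: float = 2.25e-4
    re_cov_intercept_slope: float = 0.0
    # fitting options
    n_quad: int = 7
    bootstrap_reps: int = 200
    bayes_bootstrap_reps: int = 200
    prior_constraint: float = bayes_fit.DEFAULT_PRIOR_VARIANCE
    n_starts: int = 5
    # I/O
    trials_path: str | None = None
    out_dir: str | None = None

    def observer_params(self) -> ObserverParams:
        return ObserverParams.single_prior(
            self.sigma2_prior,
            self.sigma2_prop,
            self.sigma2_tact,
            v_pursuit=self.v_pursuit,
            kappa_low_amp=self.kappa_low_amp,
        )

    def re_cov(self) -> np.ndarray:
        return np.array(
            [
                [self.re_var_intercept, self.re_cov_intercept_slope],
                [self.re_cov_intercept_slope, self.re_var_slope],
            ]
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _simulate_trials(config: RunConfig) -> pd.DataFrame:
    design = synth.make_design(config.experiment, seed=config.seed, pursuit_speed=config.v_pursuit)
    conditions = sorted(design["condition"].unique())
    spec = synth.population_from_observer(
        config.observer_params(), conditions, config.re_cov(), config.n_observers
    )
    return synth.simulate_population(spec, design, seed=config.seed + 1)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and optionally writes) the report."""
    if config.trials_path:
        trials = read_trials(config.trials_path)
    else:
        trials = _simulate_trials(config)

    conditions = sorted(trials["condition"].unique())
    report: dict = {
        "config": dataclasses.asdict(config),
        "n_trials": int(len(trials)),
        "conditions": conditions,
    }

    # stage 1: per-observer descriptive probits
    per_observer = []
    for (obs, cond), grp in trials.groupby(["observer_id", "condition"]):
        try:
            fit = psychometrics.fit_probit_ml(grp)
        except ValueError as exc:
            per_observer.append({"observer_id": obs, "condition": cond, "excluded": str(exc)})
            continue
        per_observer.append(
            {
                "observer_id": obs,
                "condition": cond,
                "intercept": fit.intercept,
                "slope": fit.slope,
                "pse": fit.pse if not fit.separation else None,
                "jnd": fit.jnd if not fit.separation else None,
                "separation": fit.separation,
            }
        )
    report["per_observer"] = per_observer

    # stage 2: hierarchical fit and bootstrap PSE intervals
    hfit = hierarchical.fit_hierarchical_probit(trials, conditions=conditions, n_quad=config.n_quad)
    report["hierarchical"] = {
        "fixed_effects": {c: list(map(float, fe)) for c, fe in hfit.fixed_effects.items()},
        "re_cov": hfit.re_cov.tolist(),
        "pse": {c: float(p) for c, p in hfit.pse.items()},
        "loglik": hfit.loglik,
        "converged": hfit.converged,
    }
    if config.bootstrap_reps > 0:
        # one replicate set serves both the per-condition CIs and the difference
        reps, n_failed = hierarchical._bootstrap_replicates(hfit, config.bootstrap_reps, config.seed + 2)
        report["hierarchical"]["pse_ci"] = {}
        for j, c in enumerate(hfit.conditions):
            lo, hi = np.percentile(reps[:, j], [2.5, 97.5])
            report["hierarchical"]["pse_ci"][c] = {"low": float(lo), "high": float(hi), "n_failed": n_failed}
        if len(conditions) == 2:
            diff = reps[:, 0] - reps[:, 1]
            lo, hi = np.percentile(diff, [2.5, 97.5])
            report["hierarchical"]["pse_difference"] = {
                "conditions": list(hfit.conditions),
                "estimate": float(hfit.pse[hfit.conditions[0]] - hfit.pse[hfit.conditions[1]]),
                "low": float(lo),
                "high": float(hi),
                "significant": bool(lo > 0.0 or hi < 0.0),
            }

    # stage 3: constrained Bayesian observer fit (+ population bootstrap)
    bfit = bayes_fit.fit_observer_model(
        trials, sigma2_prior=config.prior_constraint, n_starts=config.n_starts, seed=config.seed + 4
    )
    report["bayes"] = {
        "sigma2_prop": bfit.sigma2_prop,
        "sigma2_tact": bfit.sigma2_tact,
        "sigma2_prior": bfit.sigma2_prior,
        "variance_ratio": bfit.variance_ratio,
        "predicted_pse": {c: float(p.pse) for c, p in bfit.predicted.items()},
        "predicted_slope": {c: float(p.slope) for c, p in bfit.predicted.items()},
        "converged": bfit.converged,
    }
    if config.bayes_bootstrap_reps > 0:
        probit_params = {c: tuple(hfit.fixed_effects[c]) for c in conditions}
        design = {
            c: (sorted(trials.loc[trials["condition"] == c, "v_surf"].unique()), 15)
            for c in conditions
        }
        boot = bayes_fit.parametric_bootstrap_fit(
            probit_params,
            design,
            n_reps=config.bayes_bootstrap_reps,
            seed=config.seed + 5,
            sigma2_prior=config.prior_constraint,
            v_pursuit=config.v_pursuit,
        )
        lo, hi = boot.ci("pse_main")
        report["bayes"]["bootstrap"] = {
            "pse_main_median": float(np.median(boot.pse_main)),
            "pse_main_ci": [lo, hi],
            "n_failed": boot.n_failed,
        }

    # stage 4: summary quantities
    summary: dict = {}
    main_like = next((c for c in ("main", "high_amp") if c in conditions), None)
    if main_like is not None:
        summary["filehne_gain"] = filehne_gain(hfit.pse[main_like], config.v_pursuit)
    summary["jnd"] = {
        c: float(psychometrics.Z75 / fe[1]) for c, fe in hfit.fixed_effects.items() if fe[1] > 0
    }
    report["summary"] = summary

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if not config.trials_path:
            write_trials(trials, out / "trials.csv")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        tidy = pd.DataFrame(
            [
                {
                    "condition": c,
                    "pse": report["hierarchical"]["pse"][c],
                    "ci_low": report["hierarchical"].get("pse_ci", {}).get(c, {}).get("low"),
                    "ci_high": report["hierarchical"].get("pse_ci", {}).get(c, {}).get("high"),
                }
                for c in conditions
            ]
        )
        tidy.to_csv(out / "results.csv", index=False)
    return report
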