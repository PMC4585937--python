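"""Hierarchical (mixed-effects) probit model across observers.

For observer ``i``, trial ``j`` with velocity ``v`` in condition ``c``:

    P(Y_ij = 1) = Phi( (theta0_c + u0_i) + (theta1_c + u1_i) * v ),
    (u0_i, u1_i) ~ N(0, Sigma),

i.e. condition-specific fixed intercepts/slopes plus a bivariate-Gaussian
random intercept and slope shared across conditions within an observer.
The marginal likelihood integrates the random effects out per observer;
here this is done by adaptive Gauss-Hermite quadrature (a tensor grid
re-centred and re-scaled at each observer's posterior mode, 7 nodes per
dimension by default; 1 node recovers the Laplace approximation).

The per-condition PSE is read from the fixed effects; parametric-bootstrap
percentile intervals for the PSEs and their difference come from
re-simulating whole populations from the fitted model and refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import gammaln, ndtr
from scipy.stats import norm

from .psychometrics import BootstrapResult

__all__ = [
    "HierarchicalFit",
    "bootstrap_pse_ci",
    "fit_hierarchical_probit",
    "pse_difference_ci",
]

_PCLIP = 1e-12
_LOG_CHOL_BOUNDS = (-8.0, 4.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _npdf(x: np.ndarray) -> np.ndarray:
    return _INV_SQRT_2PI * np.exp(-0.5 * x * x)


@dataclass
class _PanelData:
    """Per-observer aggregated counts padded to a rectangular layout."""

    observers: list[str]
    k: np.ndarray  # (N, M) successes
    n: np.ndarray  # (N, M) trials (0 = padding)
    v: np.ndarray  # (N, M) velocities
    cond: np.ndarray  # (N, M) condition index
    conditions: tuple[str, ...]

    @property
    def n_observers(self) -> int:
        return len(self.observers)

    @property
    def n_trials(self) -> int:
        return int(self.n.sum())

    @property
    def binom_const(self) -> np.ndarray:
        return (gammaln(self.n + 1) - gammaln(self.k + 1) - gammaln(self.n - self.k + 1)).sum(axis=1)


def _build_panel(trials: pd.DataFrame, conditions: Sequence[str] | None) -> _PanelData:
    cells = (
        trials.groupby(["observer_id", "condition", "v_surf"])["response"]
        .agg(["sum", "count"])
        .reset_index()
    )
    if conditions is None:
        conditions = tuple(sorted(cells["condition"].unique()))
    else:
        conditions = tuple(conditions)
        unknown = set(cells["condition"]) - set(conditions)
        if unknown:
            raise ValueError(f"trials contain conditions not listed: {sorted(unknown)}")
    cond_index = {c: i for i, c in enumerate(conditions)}
    observers = sorted(cells["observer_id"].unique())
    groups = dict(tuple(cells.groupby("observer_id")))
    M = max(len(g) for g in groups.values())
    N = len(observers)
    k = np.zeros((N, M))
    n = np.zeros((N, M))
    v = np.zeros((N, M))
    cond = np.zeros((N, M), dtype=int)
    for i, obs in enumerate(observers):
        g = groups[obs]
        m = len(g)
        k[i, :m] = g["sum"].to_numpy()
        n[i, :m] = g["count"].to_numpy()
        v[i, :m] = g["v_surf"].to_numpy()
        cond[i, :m] = [cond_index[c] for c in g["condition"]]
    return _PanelData(observers=list(observers), k=k, n=n, v=v, cond=cond, conditions=conditions)


@dataclass
class HierarchicalFit:
    """Fitted mixed-effects probit model."""

    conditions: tuple[str, ...]
    fixed_effects: dict
    re_cov: np.ndarray
    loglik: float
    n_params: int
    n_trials: int
    converged: bool
    message: str
    n_quad: int
    equal_slopes: bool
    n_observers: int
    _panel: _PanelData = field(repr=False, default=None)
    _theta: np.ndarray = field(repr=False, default=None)

    @property
    def pse(self) -> dict:
        return {c: -b0 / b1 for c, (b0, b1) in self.fixed_effects.items()}

    @property
    def re_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.re_cov))


class _MarginalNLL:
    """Negative marginal log-likelihood with adaptive Gauss-Hermite panels.

    Posterior modes are cached between evaluations (warm starts), which
    cuts the inner Newton iterations to a handful once the optimiser is in
    the neighbourhood of the optimum.
    """

    def __init__(self, panel: _PanelData, n_quad: int = 7, equal_slopes: bool = False):
        self.panel = panel
        self.n_quad = int(n_quad)
        self.equal_slopes = bool(equal_slopes)
        self.n_cond = len(panel.conditions)
        nodes, weights = hermgauss(self.n_quad)
        zx, zy = np.meshgrid(nodes, nodes, indexing="ij")
        self.zx = zx.ravel()
        self.zy = zy.ravel()
        wx, wy = np.meshgrid(weights, weights, indexing="ij")
        self.logw = np.log(wx.ravel()) + np.log(wy.ravel())
        self.z2 = self.zx**2 + self.zy**2
        self._u = np.zeros((panel.n_observers, 2))
        self._binom_const = panel.binom_const

    # -- parameter packing ---------------------------------------------
    @property
    def n_fixed(self) -> int:
        return self.n_cond + 1 if self.equal_slopes else 2 * self.n_cond

    @property
    def n_params(self) -> int:
        return self.n_fixed + 3

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if self.equal_slopes:
            b0 = theta[: self.n_cond]
            b1 = np.full(self.n_cond, theta[self.n_cond])
        else:
            b0 = theta[: 2 * self.n_cond : 2]
            b1 = theta[1 : 2 * self.n_cond : 2]
        t = theta[self.n_fixed :]
        lo, hi = _LOG_CHOL_BOUNDS
        L = np.array([[math.exp(min(max(t[0], lo), hi)), 0.0], [t[1], math.exp(min(max(t[2], lo), hi))]])
        return b0, b1, L

    def pack(self, fixed: dict, re_cov: np.ndarray) -> np.ndarray:
        conds = self.panel.conditions
        if self.equal_slopes:
            head = [fixed[c][0] for c in conds] + [np.mean([fixed[c][1] for c in conds])]
        else:
            head = []
            for c in conds:
                head.extend(fixed[c])
        L = np.linalg.cholesky(np.asarray(re_cov) + 1e-10 * np.eye(2))
        return np.array(head + [math.log(L[0, 0]), L[1, 0], math.log(L[1, 1])])

    # -- likelihood ----------------------------------------------------
    def _eta_fixed(self, b0: np.ndarray, b1: np.ndarray) -> np.ndarray:
        return b0[self.panel.cond] + b1[self.panel.cond] * self.panel.v

    def _modes(self, eta_fixed: np.ndarray, Sinv: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised Fisher-scoring search for the posterior modes."""
        p_ = self.panel
        u = self._u.copy()
        for _ in range(60):
            eta = eta_fixed + u[:, [0]] + u[:, [1]] * p_.v
            cdf = np.clip(ndtr(eta), _PCLIP, 1 - _PCLIP)
            pdf = _npdf(eta)
            r = pdf * (p_.k / cdf - (p_.n - p_.k) / (1 - cdf))
            W = p_.n * pdf**2 / (cdf * (1 - cdf))
            g0 = r.sum(1) - (Sinv[0, 0] * u[:, 0] + Sinv[0, 1] * u[:, 1])
            g1 = (r * p_.v).sum(1) - (Sinv[0, 1] * u[:, 0] + Sinv[1, 1] * u[:, 1])
            A = W.sum(1) + Sinv[0, 0]
            Bm = (W * p_.v).sum(1) + Sinv[0, 1]
            C = (W * p_.v**2).sum(1) + Sinv[1, 1]
            det = A * C - Bm**2
            du0 = (C * g0 - Bm * g1) / det
            du1 = (A * g1 - Bm * g0) / det
            # damp very large first steps
            norm_step = np.maximum(1.0, np.maximum(np.abs(du0), np.abs(du1)) / 3.0)
            u[:, 0] += du0 / norm_step
            u[:, 1] += du1 / norm_step
            if max(np.max(np.abs(du0)), np.max(np.abs(du1))) < 1e-9:
                break
        self._u = u.copy()
        # Fisher information at the mode (used to scale the quadrature grid)
        eta = eta_fixed + u[:, [0]] + u[:, [1]] * p_.v
        cdf = np.clip(ndtr(eta), _PCLIP, 1 - _PCLIP)
        pdf = _npdf(eta)
        W = p_.n * pdf**2 / (cdf * (1 - cdf))
        A = W.sum(1) + Sinv[0, 0]
        Bm = (W * p_.v).sum(1) + Sinv[0, 1]
        C = (W * p_.v**2).sum(1) + Sinv[1, 1]
        return u, A, Bm, C

    def _h(self, eta_fixed: np.ndarray, u0: np.ndarray, u1: np.ndarray, Sinv: np.ndarray) -> np.ndarray:
        """Unnormalised log joint: binomial loglik plus Gaussian exponent."""
        p_ = self.panel
        eta = eta_fixed[:, None, :] + u0[:, :, None] + u1[:, :, None] * p_.v[:, None, :]
        cdf = np.clip(ndtr(eta), _PCLIP, 1 - _PCLIP)
        ll = (p_.k[:, None, :] * np.log(cdf) + (p_.n - p_.k)[:, None, :] * np.log1p(-cdf)).sum(-1)
        quad = 0.5 * (Sinv[0, 0] * u0**2 + 2 * Sinv[0, 1] * u0 * u1 + Sinv[1, 1] * u1**2)
        return ll - quad

    def loglik_by_observer(self, theta: np.ndarray) -> np.ndarray:
        b0, b1, L = self.unpack(theta)
        S = L @ L.T
        detS = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[0, 1], S[0, 0]]]) / detS
        eta_fixed = self._eta_fixed(b0, b1)
        uhat, A, Bm, C = self._modes(eta_fixed, Sinv)
        detG = A * C - Bm**2
        # closed-form Cholesky of the inverse information
        iA, iB, iC = C / detG, -Bm / detG, A / detG
        C00 = np.sqrt(iA)
        C10 = iB / C00
        C11 = np.sqrt(np.maximum(iC - C10**2, 1e-300))
        u0 = uhat[:, [0]] + math.sqrt(2.0) * C00[:, None] * self.zx[None, :]
        u1 = uhat[:, [1]] + math.sqrt(2.0) * (C10[:, None] * self.zx[None, :] + C11[:, None] * self.zy[None, :])
        h = self._h(eta_fixed, u0, u1, Sinv)
        m = h.max(axis=1)
        log_integral = np.log(np.exp(h - m[:, None] + self.z2 + self.logw).sum(axis=1)) + m
        log_detC = np.log(C00) + np.log(C11)
        return (
            -math.log(2 * math.pi)
            - 0.5 * math.log(detS)
            + math.log(2.0)
            + log_detC
            + log_integral
            + self._binom_const
        )

    def __call__(self, theta: np.ndarray) -> float:
        ll = self.loglik_by_observer(theta)
        if not np.all(np.isfinite(ll)):
            return 1e10
        return -float(ll.sum())


def _pooled_probit_start(panel: _PanelData) -> dict:
    """Per-condition pooled probit fits used as starting fixed effects."""
    from .psychometrics import batch_probit_counts

    fixed = {}
    for ci, cond in enumerate(panel.conditions):
        mask = (panel.cond == ci) & (panel.n > 0)
        v = panel.v[mask]
        levels = np.unique(v)
        k = np.array([panel.k[mask][v == lv].sum() for lv in levels])
        n = np.array([panel.n[mask][v == lv].sum() for lv in levels])
        X = np.column_stack([np.ones_like(levels), levels])
        beta, _ = batch_probit_counts(k[None, :], n, X)
        fixed[cond] = (float(beta[0, 0]), float(beta[0, 1]))
    return fixed


def fit_hierarchical_probit(
    trials: pd.DataFrame,
    conditions: Sequence[str] | None = None,
    n_quad: int = 7,
    equal_slopes: bool = False,
    start: np.ndarray | None = None,
    re_cov_start: np.ndarray | None = None,
    maxiter: int = 4000,
    xatol: float = 1e-5,
    fatol: float = 1e-7,
) -> HierarchicalFit:
    """Marginal maximum likelihood for the mixed-effects probit model.

    ``equal_slopes=True`` constrains the fixed slope to be common across
    conditions (the reduced model of the slope likelihood-ratio test).
    ``start`` accepts a packed parameter vector (e.g. from a previous fit)
    to warm-start bootstrap refits.
    """
    panel = _build_panel(trials, conditions)
    return _fit_panel(
        panel,
        n_quad=n_quad,
        equal_slopes=equal_slopes,
        start=start,
        re_cov_start=re_cov_start,
        maxiter=maxiter,
        xatol=xatol,
        fatol=fatol,
    )


def _fit_panel(
    panel: _PanelData,
    n_quad: int = 7,
    equal_slopes: bool = False,
    start: np.ndarray | None = None,
    re_cov_start: np.ndarray | None = None,
    maxiter: int = 4000,
    xatol: float = 1e-5,
    fatol: float = 1e-7,
) -> HierarchicalFit:
    if panel.n_observers < 2:
        raise ValueError("hierarchical fit needs >= 2 observers")
    nll = _MarginalNLL(panel, n_quad=n_quad, equal_slopes=equal_slopes)
    if start is None:
        fixed0 = _pooled_probit_start(panel)
        cov0 = np.diag([0.05, 1e-4]) if re_cov_start is None else np.asarray(re_cov_start)
        theta0 = nll.pack(fixed0, cov0)
    else:
        theta0 = np.asarray(start, dtype=float)
    res = minimize(
        nll,
        theta0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "maxfev": maxiter, "xatol": xatol, "fatol": fatol},
    )
    b0, b1, L = nll.unpack(res.x)
    fixed = {c: (float(b0[i]), float(b1[i])) for i, c in enumerate(panel.conditions)}
    fit = HierarchicalFit(
        conditions=panel.conditions,
        fixed_effects=fixed,
        re_cov=L @ L.T,
        loglik=-float(res.fun),
        n_params=nll.n_params,
        n_trials=panel.n_trials,
        converged=bool(res.success),
        message=str(res.message),
        n_quad=n_quad,
        equal_slopes=equal_slopes,
        n_observers=panel.n_observers,
        _panel=panel,
        _theta=np.asarray(res.x, dtype=float),
    )
    return fit


def _simulate_panel(fit: HierarchicalFit, rng: np.random.Generator) -> _PanelData:
    """Parametric re-simulation of the fitted population on its own design."""
    panel = fit._panel
    chol = np.linalg.cholesky(fit.re_cov + 1e-12 * np.eye(2))
    u = rng.standard_normal((panel.n_observers, 2)) @ chol.T
    beta0 = np.array([fit.fixed_effects[c][0] for c in panel.conditions])
    beta1 = np.array([fit.fixed_effects[c][1] for c in panel.conditions])
    eta = beta0[panel.cond] + beta1[panel.cond] * panel.v + u[:, [0]] + u[:, [1]] * panel.v
    p = norm.cdf(eta)
    k = rng.binomial(panel.n.astype(int), p).astype(float)
    return _PanelData(
        observers=panel.observers,
        k=k,
        n=panel.n,
        v=panel.v,
        cond=panel.cond,
        conditions=panel.conditions,
    )


def _bootstrap_replicates(
    fit: HierarchicalFit, n_reps: int, seed: int | None
) -> tuple[np.ndarray, int]:
    """PSE replicates (n_ok, n_conditions) from the parametric bootstrap."""
    rng = np.random.default_rng(seed)
    reps = []
    failures = 0
    for _ in range(n_reps):
        sim = _simulate_panel(fit, rng)
        try:
            refit = _fit_panel(
                sim,
                n_quad=fit.n_quad,
                equal_slopes=fit.equal_slopes,
                start=fit._theta,
                maxiter=1500,
                xatol=1e-3,
                fatol=1e-5,
            )
            pse = [refit.pse[c] for c in fit.conditions]
            if not np.all(np.isfinite(pse)):
                raise FloatingPointError("non-finite PSE")
            reps.append(pse)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            failures += 1
    return np.asarray(reps), failures


def bootstrap_pse_ci(
    fit: HierarchicalFit, n_reps: int = 1000, seed: int | None = None
) -> dict:
    """Percentile bootstrap 95% CIs for the per-condition PSEs.

    Each replicate simulates a full population from the fitted model
    (random effects redrawn, responses binomial on the original design)
    and refits; failed replicate fits are excluded and counted.
    """
    reps, failures = _bootstrap_replicates(fit, n_reps, seed)
    out = {}
    for j, cond in enumerate(fit.conditions):
        col = reps[:, j]
        lo, hi = (col[0], col[0]) if len(col) == 1 else np.percentile(col, [2.5, 97.5])
        out[cond] = BootstrapResult(
            estimate=float(fit.pse[cond]),
            replicates=col,
            ci_low=float(lo),
            ci_high=float(hi),
            n_reps=n_reps,
            n_failed=failures,
            seed=seed,
        )
    return out


def pse_difference_ci(
    fit: HierarchicalFit,
    cond_a: str | None = None,
    cond_b: str | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap CI for the PSE difference ``cond_a - cond_b``.

    The difference is significant at the 5% level when the interval
    excludes zero.  Defaults to the first two fitted conditions.
    """
    if cond_a is None or cond_b is None:
        if len(fit.conditions) != 2:
            raise ValueError("specify cond_a and cond_b for fits with != 2 conditions")
        cond_a, cond_b = fit.conditions
    reps, failures = _bootstrap_replicates(fit, n_reps, seed)
    ia = fit.conditions.index(cond_a)
    ib = fit.conditions.index(cond_b)
    diff = reps[:, ia] - reps[:, ib]
    lo, hi = (diff[0], diff[0]) if len(diff) == 1 else np.percentile(diff, [2.5, 97.5])
    return BootstrapResult(
        estimate=float(fit.pse[cond_a] - fit.pse[cond_b]),
        replicates=diff,
        ci_low=float(lo),
        ci_high=float(hi),
        n_reps=n_reps,
        n_failed=failures,
        seed=seed,
    )
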