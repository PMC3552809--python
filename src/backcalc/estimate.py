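"""Maximum-likelihood estimation of yearly incidence h_t and registration
probability p_t.

The Poisson likelihood is maximized directly over the transformed
parameters ``a_t = log h_t`` (every grid year) and a scaled logit of
``p_t`` (observation-window years only), which enforces ``h_t >= 0`` and
``0 < p_t < 1 - q_t`` smoothly.  Registration probabilities before the
observation window are not free: they are fixed by a flat level (no
specific treatment on offer) followed by a linear ramp up to the value of
``p`` in the first observed year.  Because that link value is itself a
free parameter, the ramp is recomputed inside every objective evaluation
and its gradient contribution is chained through — the pre-window
assumption and the estimate stay mutually consistent.  A two-stage
variant (fit, freeze the ramp at the fitted link value, refit) is
available for comparison.

Optimization uses L-BFGS-B with an analytic gradient.  For the gradient,
with D_ij = N_ij - mu_ij over observed cells,

    dL/d log h_i = sum_j D_ij
    dL/d p_m     = (sum_i D_im)/p_m - (sum_{i<=m<j} D_ij)/(1-p_m-q_m)

the second term collecting every cell whose survival product crosses
year m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .model import (
    CountMatrix,
    ExpectedMatrix,
    LeavingSchedule,
    ModelError,
    ParameterVector,
    YearGrid,
    _mu_matrix,
    log_likelihood,
)
from .rates import Scenario

logger = logging.getLogger(__name__)

__all__ = [
    "PreObsRule",
    "FitSettings",
    "FitResult",
    "apply_pre_obs_rule",
    "fit",
    "ridge_member",
]


@dataclass(frozen=True)
class PreObsRule:
    """Registration probabilities before the observation window.

    ``p_t = flat_value`` for ``t <= flat_until``; from ``ramp_from``
    onward p rises linearly, reaching the (estimated) link-year value at
    ``link_year`` (the first observed year).  Default layout: flat 0.01
    through 1981, ramp over 1982-1990, linked to p in 1991.
    """

    flat_value: float = 0.01
    flat_until: int = 1981
    ramp_from: int = 1982

    def __post_init__(self) -> None:
        if not (0.0 < self.flat_value < 1.0):
            raise ModelError("flat_value must lie in (0, 1)")
        if self.flat_until >= self.ramp_from:
            raise ModelError("flat_until must precede ramp_from")


def apply_pre_obs_rule(rule: PreObsRule, p_link: float, grid: YearGrid) -> np.ndarray:
    """p_t for every year before the observation window (may be empty).

    The ramp interpolates linearly between ``flat_value`` at
    ``flat_until`` and ``p_link`` at the first observed year.
    """
    if not (0.0 < p_link < 1.0):
        raise ModelError("p_link must lie in (0, 1)")
    link_year = grid.first_obs_year
    if rule.ramp_from > link_year:
        raise ModelError("ramp_from must not exceed the first observed year")
    years = np.arange(grid.first_onset_year, link_year)
    w = _ramp_weights(rule, grid)
    return rule.flat_value + w * (p_link - rule.flat_value)


def _ramp_weights(rule: PreObsRule, grid: YearGrid) -> np.ndarray:
    """dp_t/dp_link for pre-window years: 0 on the flat segment, linear on the ramp."""
    link_year = grid.first_obs_year
    years = np.arange(grid.first_onset_year, link_year)
    w = (years - rule.flat_until) / (link_year - rule.flat_until)
    return np.clip(w, 0.0, 1.0)


@dataclass(frozen=True)
class FitSettings:
    """Optimizer configuration.

    tol is the relative log-likelihood change declaring convergence;
    gtol the projected-gradient threshold in the transformed space.
    ``p_init`` seeds both the flat p start and the moment start for h
    (observed treatments per cohort inflated by 1/p_init).  ``fixed_p``
    pins chosen observation-window years to known values (useful for
    closed-form checks and profile analyses).  ``weak_threshold`` is the
    observed-treatment count below which a cohort's h is flagged as
    weakly identified.
    """

    tol: float = 1e-9
    gtol: float = 1e-8
    maxiter: int = 10_000
    p_init: float = 0.1
    fixed_p: Optional[Mapping[int, float]] = None
    two_stage: bool = False
    weak_threshold: int = 50


@dataclass
class FitResult:
    params: ParameterVector
    loglik: float
    converged: bool
    n_iterations: int
    mu_hat: ExpectedMatrix
    settings: FitSettings
    grad_norm: float
    message: str
    scenario: Optional[Scenario] = None
    leaving: Optional[LeavingSchedule] = None
    cohort_observed: Optional[np.ndarray] = None
    weakly_identified: Optional[list] = None

    def to_frame(self):
        """Per-year table: year, h_hat, p_hat, q_used."""
        import pandas as pd

        df = pd.DataFrame(
            {"year": self.params.grid.years, "h_hat": self.params.h, "p_hat": self.params.p}
        )
        if self.leaving is not None:
            df["q_used"] = self.leaving.q
        return df


def ridge_member(
    params: ParameterVector,
    leaving: LeavingSchedule,
    rule: PreObsRule,
    r0: float,
) -> ParameterVector:
    """A different (h, p) with *identical* expected counts on observed cells.

    The likelihood determines (h, p) jointly only up to an exact
    one-parameter family: for any feasible ``r0 > 0``, setting

        p'_k = p_k / r_k,   h'_k = h_k * r_k,
        r_{k+1} = r_k * (1 - p'_k - q_k) / (1 - p_k - q_k)

    over the observation window (with ``r`` at the first observed year
    equal to ``r0``), re-linking the pre-window ramp to the new link
    value and rescaling pre-window h to absorb the changed pre-window
    survival, leaves every mu_ij unchanged — and therefore the
    likelihood of any data.  ``r0 = 1`` returns the input.  Consequence:
    a point estimate of (h, p) is only meaningful once the gauge is
    fixed, e.g. by pinning p in one year to an externally known value
    (``FitSettings.fixed_p``); without that, only mu-functionals (fitted
    counts, deviances, lag distributions) are identified.

    Raises :class:`ModelError` if the requested member leaves the
    feasible region (some ``p'`` outside ``(0, 1 - q)``).
    """
    if r0 <= 0:
        raise ModelError("r0 must be positive")
    grid = params.grid
    T = grid.n_years
    obs0 = grid.index(grid.first_obs_year)
    h, p, q = params.h, params.p, leaving.q
    h2 = h.copy()
    p2 = p.copy()
    r = r0
    for k in range(obs0, T):
        p2[k] = p[k] / r
        if not (0.0 < p2[k] < 1.0 - q[k]):
            raise ModelError(f"ridge member infeasible at year {grid.years[k]}")
        h2[k] = h[k] * r
        if k + 1 < T:
            r = r * (1.0 - p2[k] - q[k]) / (1.0 - p[k] - q[k])
    if obs0 > 0:
        p2[:obs0] = apply_pre_obs_rule(rule, p2[obs0], grid)
        s_old = 1.0 - p[:obs0] - q[:obs0]
        s_new = 1.0 - p2[:obs0] - q[:obs0]
        if np.any(s_new <= 0):
            raise ModelError("ridge member infeasible in the pre-window years")
        # A_i = prod_{k=i}^{obs0-1} s_k ; h'_i = h_i * (A_i / A'_i) * r0
        A_old = np.cumprod(s_old[::-1])[::-1]
        A_new = np.cumprod(s_new[::-1])[::-1]
        h2[:obs0] = h[:obs0] * (A_old / A_new) * r0
    return ParameterVector(grid, h2, p2)


def _objective_factory(
    counts: CountMatrix,
    leaving: LeavingSchedule,
    rule: PreObsRule,
    fixed_p: Optional[Mapping[int, float]],
    frozen_link: Optional[float],
):
    """Build (negative loglik, gradient) in the transformed parameter space.

    Returns (fun, pack, unpack_p, free_idx) where ``pack`` maps natural
    (h, p_obs) starts to a theta vector and ``unpack_p`` recovers the
    full p series from theta.
    """
    grid = counts.grid
    T = grid.n_years
    obs0 = grid.index(grid.first_obs_year)
    q = leaving.q
    mask = grid.observed_cell_mask()
    N = np.where(mask, counts.counts, 0).astype(float)
    w_ramp = _ramp_weights(rule, grid)  # length obs0

    fixed = {} if fixed_p is None else {grid.index(y): float(v) for y, v in fixed_p.items()}
    for k, v in fixed.items():
        if k < obs0:
            raise ModelError("fixed_p applies to observation-window years only")
        if not (0.0 <= v <= 1.0 - q[k]):
            raise ModelError(f"fixed p at year {grid.years[k]} violates p + q <= 1")
    free_idx = np.array([k for k in range(obs0, T) if k not in fixed], dtype=int)
    if obs0 in fixed and frozen_link is None:
        frozen_link = fixed[obs0]

    cap = 1.0 - q  # upper bound for p in the window

    def unpack_p(theta: np.ndarray) -> np.ndarray:
        p = np.empty(T)
        p[obs0:] = 0.0
        for k, v in fixed.items():
            p[k] = v
        if free_idx.size:
            p[free_idx] = cap[free_idx] * expit(theta[T:])
        p_link = frozen_link if frozen_link is not None else p[obs0]
        p[:obs0] = rule.flat_value + w_ramp * (p_link - rule.flat_value)
        return p

    def fun(theta: np.ndarray):
        h = np.exp(theta[:T])
        p = unpack_p(theta)
        s = 1.0 - p - q
        # reparameterization guarantees s >= 0 in the window; pre-window ramp
        # values are convex combinations of flat_value and p_link, but the
        # early-year q may still push p + q past 1 for extreme link values
        if np.any(s < 0):
            return np.inf, np.zeros_like(theta)
        mu = _mu_matrix(h, p, q)
        m = np.where(mask, mu, 0.0)
        pos = N > 0
        with np.errstate(divide="ignore"):
            ll = float(np.sum(N[pos] * np.log(np.maximum(m[pos], 1e-300))) - m.sum())
        D = N - m
        grad_a = D.sum(axis=1)  # dL/d log h_i
        colsum = D.sum(axis=0)
        # suffix[i, m] = sum_{j > m} D_ij ; G_m = sum_{i <= m} suffix[i, m]
        csum = np.cumsum(D[:, ::-1], axis=1)[:, ::-1]
        suffix = np.zeros_like(D)
        suffix[:, :-1] = csum[:, 1:]
        G = np.cumsum(suffix, axis=0)[np.arange(T), np.arange(T)]
        with np.errstate(divide="ignore", invalid="ignore"):
            dLdp = np.where(p > 0, colsum / np.where(p > 0, p, 1.0), 0.0)
            dLdp -= np.where(s > 0, G / np.where(s > 0, s, 1.0), 0.0)
        if frozen_link is None and obs0 > 0 and obs0 not in fixed:
            dLdp[obs0] += float(np.dot(w_ramp, dLdp[:obs0]))
        grad = np.empty_like(theta)
        grad[:T] = grad_a
        if free_idx.size:
            pk, capk = p[free_idx], cap[free_idx]
            grad[T:] = dLdp[free_idx] * pk * (capk - pk) / capk
        return -ll, -grad

    def pack(h0: np.ndarray, p0: np.ndarray) -> np.ndarray:
        theta = np.empty(T + free_idx.size)
        theta[:T] = np.log(h0)
        if free_idx.size:
            frac = np.clip(p0[free_idx] / cap[free_idx], 1e-6, 1 - 1e-6)
            theta[T:] = logit(frac)
        return theta

    return fun, pack, unpack_p, free_idx


def _initial_values(counts: CountMatrix, settings: FitSettings) -> tuple[np.ndarray, np.ndarray]:
    """Moment start: observed treatments attributed to their onset cohort,
    inflated by 1/p_init; flat p_init in the window."""
    mask = counts.grid.observed_cell_mask()
    row = np.where(mask, counts.counts, 0).sum(axis=1).astype(float)
    scale = max(row.mean(), 1.0)
    h0 = np.maximum(row / settings.p_init, 0.05 * scale)
    p0 = np.full(counts.grid.n_years, settings.p_init)
    return h0, p0


def fit(
    counts: CountMatrix,
    leaving: LeavingSchedule,
    rule: PreObsRule = PreObsRule(),
    settings: FitSettings | None = None,
    scenario: Optional[Scenario] = None,
    h0: Optional[np.ndarray] = None,
    p0: Optional[np.ndarray] = None,
) -> FitResult:
    """Maximize the Poisson likelihood over (h_t, p_t).

    Raises :class:`ModelError` on all-zero data.  Non-convergence is
    reported via ``converged=False`` with the best point found.
    """
    settings = settings or FitSettings()
    if counts.grid != leaving.grid:
        raise ModelError("counts and schedule are on different grids")
    if counts.observed_total == 0:
        raise ModelError("no positive observed counts; nothing to fit")

    if settings.two_stage:
        first = fit(counts, leaving, rule, replace(settings, two_stage=False), scenario)
        frozen = float(first.params.p[counts.grid.index(counts.grid.first_obs_year)])
        return _fit_once(counts, leaving, rule, settings, scenario, frozen, h0, p0)
    return _fit_once(counts, leaving, rule, settings, scenario, None, h0, p0)


def _fit_once(counts, leaving, rule, settings, scenario, frozen_link, h0, p0) -> FitResult:
    grid = counts.grid
    T = grid.n_years
    fun, pack, unpack_p, free_idx = _objective_factory(
        counts, leaving, rule, settings.fixed_p, frozen_link
    )
    h_init, p_init = _initial_values(counts, settings)
    if h0 is not None:
        h_init = np.asarray(h0, dtype=float)
    if p0 is not None:
        p_init = np.asarray(p0, dtype=float)
    theta0 = pack(h_init, p_init)

    res = optimize.minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={
            "ftol": settings.tol,
            "gtol": settings.gtol,
            "maxiter": settings.maxiter,
            "maxfun": 10 * settings.maxiter,
            "maxls": 50,
        },
    )
    h_hat = np.exp(res.x[:T])
    p_hat = unpack_p(res.x)
    params = ParameterVector(grid, h_hat, p_hat)
    mu_hat = ExpectedMatrix(grid, _mu_matrix(h_hat, p_hat, leaving.q))
    ll = log_likelihood(counts, mu_hat)
    mask = grid.observed_cell_mask()
    cohort_obs = np.where(mask, counts.counts, 0).sum(axis=1)
    weak = grid.years[cohort_obs < settings.weak_threshold].tolist()
    converged = bool(res.success)
    if not converged:
        logger.warning("optimizer did not converge: %s", res.message)
    return FitResult(
        params=params,
        loglik=ll,
        converged=converged,
        n_iterations=int(res.nit),
        mu_hat=mu_hat,
        settings=settings,
        grad_norm=float(np.max(np.abs(res.jac))),
        message=str(res.message),
        scenario=scenario,
        leaving=leaving,
        cohort_observed=cohort_obs,
        weakly_identified=weak,
    )
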