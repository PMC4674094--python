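"""Individual-level survival variant of the dose-response analysis.

Instead of summarizing each treatment group to an inverse mean lifespan, the
Cox model uses every animal's lifespan directly. The hazard in stratum s is

    h_i(t) = h_s(t) * exp(alpha_s * (dose_i + theta * dose_i^2 / fractions_i) + Z_g),

with a baseline h_s(t) stratified by analysis stratum (risk sets never cross
strata), per-stratum linear coefficients alpha_s optionally restricted to
positive values, and a Gaussian group-level random effect Z_g on the
log-hazard scale. The frailty variance is estimated by maximizing the
Laplace-approximate integrated partial likelihood; theta is profiled over the
same DDREF grid and the same 1.92 log-likelihood-unit interval rule as the
group-level regression.

Ties are handled with Breslow's approximation by default (Efron available
behind an option flag).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .data_model import AnimalRecord, StratumKey
from .lq_profile import (
    PROFILE_DROP,
    DdrefEstimate,
    GridSpec,
    RatioPoint,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CoxLqFit",
    "CoxOptions",
    "survival_records",
    "km_curve",
    "cox_partial_loglik",
    "fit_cox_lq",
    "profile_cox_ddref",
]


@dataclass(frozen=True)
class SurvivalRecord:
    time: float  # days
    event: bool
    stratum: StratumKey
    group_id: str
    dose: float  # Gy
    fractions: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be > 0, got {self.time}")


def survival_records(
    animals: Sequence[AnimalRecord], by_study: bool = False
) -> list[SurvivalRecord]:
    out = []
    for a in animals:
        key = a.stratum.with_study(a.study_id) if by_study else a.stratum
        out.append(
            SurvivalRecord(
                time=a.lifespan, event=a.event, stratum=key,
                group_id=a.group_id, dose=a.total_dose, fractions=a.fractions,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate for one group: step function S(t)."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t+) after each event time
    at_risk: np.ndarray  # risk-set size just before each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_curve(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit estimator; censored records shrink the risk set only."""
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    out_t, out_s, out_r = [], [], []
    s = 1.0
    n = len(times)
    i = 0
    while i < n:
        t = times[i]
        j = i
        deaths = 0
        while j < n and times[j] == t:
            deaths += int(events[j])
            j += 1
        at_risk = n - i
        if deaths > 0:
            s *= 1.0 - deaths / at_risk
            out_t.append(t)
            out_s.append(s)
            out_r.append(at_risk)
        i = j
    return KMCurve(
        times=np.array(out_t), survival=np.array(out_s), at_risk=np.array(out_r)
    )


# ---------------------------------------------------------------------------
# Cox machinery

@dataclass
class _StratumData:
    """One stratum's records, sorted by time ascending, with group codes."""

    times: np.ndarray
    events: np.ndarray  # bool
    dose: np.ndarray
    quad: np.ndarray  # dose^2 / fractions
    group_codes: np.ndarray  # indices into the global group list
    death_index: np.ndarray  # row index ranges per unique death time
    death_counts: np.ndarray
    n_events: int


def _prepare(records: Sequence[SurvivalRecord]):
    """Group records by stratum; assign global group codes."""
    strata_keys: list[StratumKey] = []
    group_ids: list[str] = []
    group_code: dict[str, int] = {}
    by_stratum: dict[StratumKey, list[SurvivalRecord]] = {}
    for r in records:
        by_stratum.setdefault(r.stratum, []).append(r)
        if r.group_id not in group_code:
            group_code[r.group_id] = len(group_ids)
            group_ids.append(r.group_id)

    data: dict[StratumKey, _StratumData] = {}
    for key, recs in by_stratum.items():
        t = np.array([r.time for r in recs])
        order = np.argsort(t, kind="stable")
        t = t[order]
        ev = np.array([recs[i].event for i in order], dtype=bool)
        dose = np.array([recs[i].dose for i in order])
        frac = np.array([recs[i].fractions for i in order], dtype=float)
        codes = np.array([group_code[recs[i].group_id] for i in order])
        death_times = np.unique(t[ev])
        # first row index at each death time, and tied-death counts
        starts = np.searchsorted(t, death_times, side="left")
        counts = np.array([int(ev[t == dt].sum()) for dt in death_times])
        n_events = int(ev.sum())
        if n_events == 0:
            logger.warning("stratum %s has zero events; contributes 0", key)
        data[key] = _StratumData(
            times=t, events=ev, dose=dose, quad=dose * dose / frac,
            group_codes=codes, death_index=starts, death_counts=counts,
            n_events=n_events,
        )
        strata_keys.append(key)
    return data, group_ids


def _effective_covariate(sd: _StratumData, theta: float) -> np.ndarray:
    if math.isinf(theta):
        return sd.quad
    return sd.dose + theta * sd.quad


def _breslow_pl_grad(sd: _StratumData, eta: np.ndarray):
    """Breslow partial log-likelihood and its gradient w.r.t. eta.

    Records are sorted ascending in time, so the risk set at death time t_k
    is the suffix starting at the first record with time >= t_k.
    """
    if sd.n_events == 0:
        return 0.0, np.zeros_like(eta)
    ex = np.exp(eta)
    # suffix sums: risk_sum[i] = sum_{j >= i} exp(eta_j)
    risk_sum = np.cumsum(ex[::-1])[::-1]
    s_k = risk_sum[sd.death_index]
    d_k = sd.death_counts
    pl = float(eta[sd.events].sum() - (d_k * np.log(s_k)).sum())

    # grad_j = event_j - exp(eta_j) * sum_{k: t_k <= t_j} d_k / s_k
    ratio = d_k / s_k
    # cumulative ratio evaluated at each record's position:
    cum = np.zeros(len(eta) + 1)
    np.add.at(cum, sd.death_index + 1, ratio)
    cum = np.cumsum(cum)[1:]  # cum[i] = sum over death times with index <= i
    grad = sd.events.astype(float) - ex * cum
    return pl, grad


def _efron_pl_grad(sd: _StratumData, eta: np.ndarray):
    """Efron-ties partial log-likelihood and gradient (loop over death times)."""
    if sd.n_events == 0:
        return 0.0, np.zeros_like(eta)
    ex = np.exp(eta)
    risk_sum = np.cumsum(ex[::-1])[::-1]
    t = sd.times
    pl = 0.0
    grad = sd.events.astype(float)
    for start, d in zip(sd.death_index, sd.death_counts):
        dt = t[start]
        tied = (t == dt) & sd.events
        d_sum = float(ex[tied].sum())
        s = risk_sum[start]
        pl += float(eta[tied].sum())
        in_risk = np.zeros_like(eta, dtype=bool)
        in_risk[start:] = True
        for ell in range(d):
            denom = s - (ell / d) * d_sum
            pl -= math.log(denom)
            grad -= ex * (in_risk.astype(float) - (ell / d) * tied) / denom
    return pl, grad


def _pl_grad(sd: _StratumData, eta: np.ndarray, ties: str):
    if ties == "breslow":
        return _breslow_pl_grad(sd, eta)
    if ties == "efron":
        return _efron_pl_grad(sd, eta)
    raise ValueError(f"unknown ties method {ties!r}")


def cox_partial_loglik(
    records: Sequence[SurvivalRecord],
    theta: float,
    alpha_per_stratum: Mapping[StratumKey, float],
    z_per_group: Mapping[str, float] | None = None,
    ties: str = "breslow",
) -> float:
    """Stratified Cox partial log-likelihood at fixed coefficients.

    Linear predictor: alpha_s * (dose + theta*dose^2/fractions) + Z_g; at the
    pure-quadratic endpoint (theta = +inf) the covariate is dose^2/fractions.
    Risk sets are formed within strata only.
    """
    data, group_ids = _prepare(records)
    z_per_group = z_per_group or {}
    z_by_code = np.array([z_per_group.get(gid, 0.0) for gid in group_ids])
    total = 0.0
    for key, sd in data.items():
        x = _effective_covariate(sd, theta)
        eta = alpha_per_stratum[key] * x + z_by_code[sd.group_codes]
        total += _pl_grad(sd, eta, ties)[0]
    return total


@dataclass(frozen=True)
class CoxOptions:
    positive_constraints: bool = True
    frailty: bool = True
    frailty_variance: float | None = None  # fixed sigma_Z^2; None = estimate
    ties: str = "breslow"
    max_iter: int = 200


@dataclass
class CoxLqFit:
    theta: float
    alpha_per_stratum: dict[StratumKey, float]
    frailty_variance: float
    z_per_group: dict[str, float]
    log_partial_lik: float  # Laplace-integrated when frailty is on
    constrained: dict[StratumKey, bool]
    converged: bool = True


class _CoxProblem:
    """Joint optimization over per-stratum alphas and group random effects."""

    def __init__(self, records: Sequence[SurvivalRecord], options: CoxOptions):
        self.data, self.group_ids = _prepare(records)
        self.strata = list(self.data)
        self.n_strata = len(self.strata)
        self.n_groups = len(self.group_ids)
        self.options = options
        total_events = sum(sd.n_events for sd in self.data.values())
        if total_events == 0:
            raise ValueError("no events in any stratum; Cox model undefined")

    def covariates(self, theta: float) -> dict[StratumKey, np.ndarray]:
        return {k: _effective_covariate(sd, theta) for k, sd in self.data.items()}

    def neg_penalized(self, params: np.ndarray, xs, sigma2: float, use_z: bool):
        """-pl + |z|^2/(2 sigma2), with gradient."""
        alphas = params[: self.n_strata]
        z = params[self.n_strata :] if use_z else None
        value = 0.0
        grad = np.zeros_like(params)
        for i, key in enumerate(self.strata):
            sd = self.data[key]
            eta = alphas[i] * xs[key]
            if use_z:
                eta = eta + z[sd.group_codes]
            pl, g_eta = _pl_grad(sd, eta, self.options.ties)
            value -= pl
            grad[i] -= float((g_eta * xs[key]).sum())
            if use_z:
                np.add.at(grad, self.n_strata + sd.group_codes, -g_eta)
        if use_z:
            value += float((z**2).sum()) / (2.0 * sigma2)
            grad[self.n_strata :] += z / sigma2
        return value, grad

    def z_hessian(self, alphas: np.ndarray, z: np.ndarray, xs) -> np.ndarray:
        """Hessian of -pl w.r.t. the group effects z (Breslow form)."""
        H = np.zeros((self.n_groups, self.n_groups))
        for i, key in enumerate(self.strata):
            sd = self.data[key]
            if sd.n_events == 0:
                continue
            eta = alphas[i] * xs[key] + z[sd.group_codes]
            ex = np.exp(eta)
            risk_sum = np.cumsum(ex[::-1])[::-1]
            # per-group exp(eta) suffix sums
            n = len(eta)
            codes = sd.group_codes
            uniq = np.unique(codes)
            suffix_by_group = {}
            for g in uniq:
                m = np.where(codes == g, ex, 0.0)
                suffix_by_group[g] = np.cumsum(m[::-1])[::-1]
            for start, d in zip(sd.death_index, sd.death_counts):
                s = risk_sum[start]
                p = np.array([suffix_by_group[g][start] / s for g in uniq])
                block = d * (np.diag(p) - np.outer(p, p))
                H[np.ix_(uniq, uniq)] += block
        return H

    def fit_at_theta(
        self, theta: float, sigma2: float | None, x0: np.ndarray | None = None
    ):
        """Maximize the (penalized) partial likelihood at fixed theta.

        Returns (params, neg_value, xs). With frailty the return value is the
        penalized objective at the mode (Laplace pieces added by the caller).
        """
        use_z = self.options.frailty and sigma2 is not None and sigma2 > 0
        n_par = self.n_strata + (self.n_groups if use_z else 0)
        if x0 is None or len(x0) != n_par:
            x0 = np.zeros(n_par)
        xs = self.covariates(theta)

        # positivity: for finite theta < 0 the constraint beta = theta*alpha >= 0
        # pins alpha at 0 for every stratum
        pinned = (
            self.options.positive_constraints
            and not math.isinf(theta)
            and theta < 0
        )
        if self.options.positive_constraints:
            lo = 0.0
            hi = 0.0 if pinned else np.inf
            bounds = [(lo, hi)] * self.n_strata + [(-np.inf, np.inf)] * (
                n_par - self.n_strata
            )
        else:
            bounds = None

        res = optimize.minimize(
            lambda p: self.neg_penalized(p, xs, sigma2 or 1.0, use_z),
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.options.max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        return res.x, float(res.fun), xs, bool(res.success)

    def laplace_marginal(self, theta: float, sigma2: float, x0=None):
        """Laplace-approximate integrated log partial likelihood at (theta, sigma2)."""
        params, neg_pen, xs, ok = self.fit_at_theta(theta, sigma2, x0)
        alphas = params[: self.n_strata]
        z = params[self.n_strata :]
        H = self.z_hessian(alphas, z, xs) + np.eye(self.n_groups) / sigma2
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            logdet = float("inf")
        lm = -neg_pen - 0.5 * self.n_groups * math.log(sigma2) - 0.5 * logdet
        return lm, params, ok


def fit_cox_lq(
    records: Sequence[SurvivalRecord],
    theta: float,
    options: CoxOptions | None = None,
) -> CoxLqFit:
    """Fit the stratified Cox LQ model at a fixed shared ratio theta.

    Without frailty this maximizes the stratified Breslow (or Efron) partial
    likelihood over the per-stratum alphas, subject to alpha_s >= 0 when
    positivity constraints are on. With frailty, group effects z are jointly
    maximized under a Gaussian penalty and the frailty variance is chosen to
    maximize the Laplace-approximate integrated likelihood (unless fixed in
    the options). Deterministic given data and options.
    """
    options = options or CoxOptions()
    problem = _CoxProblem(records, options)

    if not options.frailty:
        params, neg, xs, ok = problem.fit_at_theta(theta, sigma2=None)
        alphas = params[: problem.n_strata]
        return CoxLqFit(
            theta=theta,
            alpha_per_stratum=dict(zip(problem.strata, map(float, alphas))),
            frailty_variance=0.0,
            z_per_group={},
            log_partial_lik=-neg,
            constrained={
                k: bool(options.positive_constraints and a <= 1e-12)
                for k, a in zip(problem.strata, alphas)
            },
            converged=ok,
        )

    if options.frailty_variance is not None:
        sigma2 = options.frailty_variance
    else:
        def negative_marginal(log_s2: float) -> float:
            lm, _, _ = problem.laplace_marginal(theta, math.exp(log_s2))
            return -lm

        res = optimize.minimize_scalar(
            negative_marginal, bounds=(math.log(1e-6), math.log(4.0)),
            method="bounded", options={"xatol": 1e-3},
        )
        sigma2 = float(math.exp(res.x))

    lm, params, ok = problem.laplace_marginal(theta, sigma2)
    alphas = params[: problem.n_strata]
    z = params[problem.n_strata :]
    return CoxLqFit(
        theta=theta,
        alpha_per_stratum=dict(zip(problem.strata, map(float, alphas))),
        frailty_variance=sigma2,
        z_per_group=dict(zip(problem.group_ids, map(float, z))),
        log_partial_lik=lm,
        constrained={
            k: bool(options.positive_constraints and a <= 1e-12)
            for k, a in zip(problem.strata, alphas)
        },
        converged=ok,
    )


DEFAULT_COX_GRID = GridSpec(n_points=101)


def profile_cox_ddref(
    records: Sequence[SurvivalRecord],
    grid: GridSpec | None = None,
    options: CoxOptions | None = None,
    subset_label: str = "all",
):
    """Profile the Cox LQ (integrated) partial likelihood over the DDREF grid.

    With frailty on, the frailty variance is estimated once at a preliminary
    theta (the no-frailty profile argmax) and held fixed across the grid; the
    1.92 log-likelihood-unit rule then gives the 95% interval. Returns
    (DdrefEstimate, grid points, log-likelihood array).
    """
    grid = grid or DEFAULT_COX_GRID
    options = options or CoxOptions()
    problem = _CoxProblem(records, options)
    points = grid.points()

    def profile(sigma2: float | None, use_z: bool) -> np.ndarray:
        ll = np.empty(len(points))
        warm: np.ndarray | None = None
        for i, pt in enumerate(points):
            if use_z:
                lm, params, _ = problem.laplace_marginal(pt.theta, sigma2, warm)
                ll[i] = lm
            else:
                params, neg, _, _ = problem.fit_at_theta(pt.theta, None, warm)
                ll[i] = -neg
            warm = params
        return ll

    if options.frailty:
        if options.frailty_variance is not None:
            sigma2 = options.frailty_variance
        else:
            base = profile(None, use_z=False)
            theta0 = points[int(np.argmax(base))].theta
            if math.isinf(theta0):
                theta0 = points[-2].theta

            def negative_marginal(log_s2: float) -> float:
                lm, _, _ = problem.laplace_marginal(theta0, math.exp(log_s2))
                return -lm

            res = optimize.minimize_scalar(
                negative_marginal, bounds=(math.log(1e-6), math.log(4.0)),
                method="bounded", options={"xatol": 1e-3},
            )
            sigma2 = float(math.exp(res.x))
        loglik = profile(sigma2, use_z=True)
    else:
        loglik = profile(None, use_z=False)

    argmax = int(np.flatnonzero(loglik >= loglik.max() - 1e-9)[0])
    mask = loglik >= loglik.max() - PROFILE_DROP - 1e-9
    ddrefs = np.array([pt.ddref for pt in points])
    inside = ddrefs[mask]
    estimate = DdrefEstimate(
        model_label="survival",
        subset_label=subset_label,
        point=float(ddrefs[argmax]),
        ci_low=float(inside[0]),
        ci_high=float(inside[-1]),
        theta_point=points[argmax].theta,
        n_groups=problem.n_groups,
        n_strata=problem.n_strata,
    )
    return estimate, points, loglik
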