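"""Shared-ratio linear-quadratic dose-response profiling.

The model for each stratum s is

    1/mean(lifespan) = intercept_s + alpha_s * (dose + theta * dose^2 / fractions) + eps

with the quadratic-to-linear ratio theta = beta/alpha constrained to a single
value across all strata. Group observations are weighted by the inverse
delta-method variance of inverse mean lifespan. For a grid of theta values
covering DDREF = 1 + theta from 0 to infinity, every stratum is refit by
weighted least squares and the weighted-Gaussian log-likelihood is summed;
the 95% credible interval consists of all grid points within 1.92
log-likelihood units (chi^2_1(0.95)/2) of the maximum.

The grid is uniform in u = DDREF/(1+DDREF) on [0, 1], so that theta = -1
(DDREF 0) and the pure-quadratic limit alpha = 0 (DDREF infinity) are both
exact grid endpoints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import GroupObservation, StratumKey

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "RatioPoint",
    "StratumFit",
    "ProfileCurve",
    "DdrefEstimate",
    "effective_dose",
    "ddref_from_theta",
    "theta_from_ddref",
    "fit_stratum_at_theta",
    "profile_loglik",
    "credible_interval",
    "estimate_ddref",
    "lrt_theta_difference",
]

PROFILE_DROP = 1.92  # chi^2_1(0.95)/2: the 95% profile-likelihood cut
_LOGLIK_TIE_EPS = 1e-9


def effective_dose(dose: float, fractions: int, theta: float):
    """Effective dose covariate x = dose + theta * dose^2 / fractions.

    Protraction into ``fractions`` acute deliveries attenuates the quadratic
    term by 1/fractions. At the pure-quadratic endpoint (theta = +inf) the
    covariate is instead dose^2/fractions with the slope reinterpreted as the
    quadratic coefficient; that endpoint is handled in
    :func:`fit_stratum_at_theta`, not here.
    """
    dose = np.asarray(dose, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    return dose + theta * dose * dose / fractions


def ddref_from_theta(theta: float, dose: float = 1.0) -> float:
    """DDREF = 1 + theta * dose; at dose 1 Gy this approximates DDREF_LSS."""
    if math.isinf(theta):
        return math.inf
    return 1.0 + theta * dose


def theta_from_ddref(ddref: float) -> float:
    if math.isinf(ddref):
        return math.inf
    return ddref - 1.0


@dataclass(frozen=True)
class RatioPoint:
    """One grid point: the ratio theta = beta/alpha and its DDREF = 1 + theta."""

    theta: float  # in [-1, +inf]; math.inf encodes the pure-quadratic model
    ddref: float

    @classmethod
    def from_u(cls, u: float) -> "RatioPoint":
        if u >= 1.0:
            return cls(theta=math.inf, ddref=math.inf)
        ddref = u / (1.0 - u)
        return cls(theta=ddref - 1.0, ddref=ddref)


@dataclass(frozen=True)
class GridSpec:
    """Uniform grid in u = DDREF/(1+DDREF) over [0, 1]."""

    n_points: int = 401

    def points(self) -> list[RatioPoint]:
        us = np.linspace(0.0, 1.0, self.n_points)
        return [RatioPoint.from_u(u) for u in us]

    def u_values(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_points)


@dataclass(frozen=True)
class StratumFit:
    """Per-stratum weighted LQ fit at a fixed shared ratio theta."""

    stratum: StratumKey
    theta: float
    alpha: float  # linear coefficient, (1/days)/Gy
    beta: float  # quadratic coefficient = theta * alpha, (1/days)/Gy^2
    intercept: float  # 1/days
    constrained: bool  # a positivity bound was active
    residuals: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)
    x: np.ndarray = field(repr=False, default=None)  # design covariate used


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted least squares of y on (1, x).

    Returns (slope, intercept). Raises on a rank-deficient design (all x equal).
    """
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    denom = sw * sxx - sx * sx
    scale = sw * max(sxx, 1e-300)
    if denom <= 1e-12 * scale:
        raise np.linalg.LinAlgError(
            "rank-deficient design: effective-dose covariate is constant"
        )
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / sw
    return slope, intercept


def fit_stratum_at_theta(
    observations: Sequence[GroupObservation],
    theta: float,
    positive_constraints: bool = False,
    stratum: StratumKey | None = None,
) -> StratumFit:
    """Weighted LS fit of one stratum at a fixed shared ratio theta.

    Under positivity constraints the feasible set is alpha >= 0 and
    beta = theta * alpha >= 0. A negative unconstrained slope — or any finite
    theta < 0, for which every alpha > 0 makes beta negative — collapses the
    fit to the boundary alpha = 0, where the intercept is the weighted mean
    of y. At the pure-quadratic endpoint (theta = +inf) the slope is the
    quadratic coefficient beta itself and alpha = 0.
    """
    if stratum is None:
        stratum = observations[0].group.stratum
    y = np.array([o.y for o in observations])
    w = np.array([o.weight for o in observations])
    dose = np.array([o.group.total_dose for o in observations])
    frac = np.array([o.group.fractions for o in observations], dtype=float)

    quad = dose * dose / frac
    pure_quadratic = math.isinf(theta)
    x = quad if pure_quadratic else dose + theta * quad

    def boundary_fit() -> StratumFit:
        intercept = float((w * y).sum() / w.sum())
        resid = y - intercept
        return StratumFit(
            stratum=stratum, theta=theta, alpha=0.0, beta=0.0,
            intercept=intercept, constrained=True,
            residuals=resid, weights=w, x=x,
        )

    if np.ptp(x) == 0.0:
        raise np.linalg.LinAlgError(
            "rank-deficient design: effective-dose covariate is constant "
            f"at theta={theta}"
        )

    if positive_constraints and not pure_quadratic and theta < 0:
        return boundary_fit()

    slope, intercept = _wls_line(x, y, w)
    if positive_constraints and slope < 0:
        return boundary_fit()

    if pure_quadratic:
        alpha, beta = 0.0, float(slope)
    else:
        alpha, beta = float(slope), float(theta * slope)
    resid = y - (intercept + slope * x)
    return StratumFit(
        stratum=stratum, theta=theta, alpha=alpha, beta=beta,
        intercept=float(intercept), constrained=False,
        residuals=resid, weights=w, x=x,
    )


@dataclass
class ProfileCurve:
    """Profile log-likelihood of the shared ratio over the DDREF grid."""

    grid: list[RatioPoint]
    loglik: np.ndarray
    argmax_index: int
    fits_at_argmax: dict[StratumKey, StratumFit]

    @property
    def max_loglik(self) -> float:
        return float(self.loglik[self.argmax_index])

    @property
    def point(self) -> RatioPoint:
        return self.grid[self.argmax_index]


def _gaussian_loglik(fits: Mapping[StratumKey, StratumFit], variances) -> float:
    total = 0.0
    for key, fit in fits.items():
        v = variances[key]
        total += float(
            (-0.5 * np.log(2.0 * np.pi * v) - 0.5 * fit.weights * fit.residuals**2).sum()
        )
    return total


def profile_loglik(
    strata_obs: Mapping[StratumKey, Sequence[GroupObservation]],
    grid: GridSpec | None = None,
    positive_constraints: bool = False,
) -> ProfileCurve:
    """Profile the weighted-Gaussian log-likelihood over the shared ratio.

    At each grid theta every stratum is refit (free per-stratum alpha and
    intercept, shared theta) and the exact weighted-Gaussian log-likelihood
    sum_g [-1/2 log(2 pi v_g) - 1/2 w_g eps_g^2] is accumulated across all
    groups. Ties at the maximum resolve to the lowest DDREF.
    """
    if not strata_obs:
        raise ValueError("no strata to fit")
    for key, obs in strata_obs.items():
        if len(obs) < 3:
            raise ValueError(f"stratum {key} has {len(obs)} groups; need >= 3")
    grid = grid or GridSpec()
    points = grid.points()

    variances = {
        key: np.array([o.variance for o in obs]) for key, obs in strata_obs.items()
    }

    loglik = np.empty(len(points))
    all_fits: list[dict[StratumKey, StratumFit]] = []
    for i, pt in enumerate(points):
        fits = {}
        for key, obs in strata_obs.items():
            try:
                fits[key] = fit_stratum_at_theta(
                    obs, pt.theta, positive_constraints, stratum=key
                )
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(f"stratum {key}: {exc}") from exc
        loglik[i] = _gaussian_loglik(fits, variances)
        all_fits.append(fits)

    # first maximizer = lowest DDREF (grid ascends in DDREF)
    argmax = int(np.flatnonzero(loglik >= loglik.max() - _LOGLIK_TIE_EPS)[0])
    return ProfileCurve(
        grid=points, loglik=loglik, argmax_index=argmax,
        fits_at_argmax=all_fits[argmax],
    )


def credible_interval(curve: ProfileCurve, drop: float = PROFILE_DROP):
    """95% profile interval on the DDREF scale.

    All grid DDREFs whose log-likelihood is within ``drop`` (1.92 =
    chi^2_1(0.95)/2) of the maximum are in the set; the interval is its
    smallest and largest member, +inf when the pure-quadratic endpoint is
    inside.
    """
    mask = curve.loglik >= curve.max_loglik - drop - _LOGLIK_TIE_EPS
    ddrefs = np.array([pt.ddref for pt in curve.grid])
    inside = ddrefs[mask]
    lo = float(inside[0])
    hi = float(inside[-1])  # np.inf when the u = 1 endpoint is in the set
    return lo, hi


@dataclass(frozen=True)
class DdrefEstimate:
    """Point estimate and 95% credible interval for one model x subset cell."""

    model_label: str
    subset_label: str
    point: float  # DDREF; may be +inf
    ci_low: float
    ci_high: float
    theta_point: float = float("nan")
    n_groups: int = 0
    n_strata: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"interval ({self.ci_low}, {self.ci_high}) does not bracket "
                f"point {self.point}"
            )


def estimate_ddref(
    strata_obs: Mapping[StratumKey, Sequence[GroupObservation]],
    grid: GridSpec | None = None,
    positive_constraints: bool = False,
    model_label: str = "beir_vii",
    subset_label: str = "all",
) -> DdrefEstimate:
    """Profile over the grid and return the DDREF point and 95% interval."""
    curve = profile_loglik(strata_obs, grid, positive_constraints)
    lo, hi = credible_interval(curve)
    n_groups = sum(len(obs) for obs in strata_obs.values())
    return DdrefEstimate(
        model_label=model_label,
        subset_label=subset_label,
        point=curve.point.ddref,
        ci_low=lo,
        ci_high=hi,
        theta_point=curve.point.theta,
        n_groups=n_groups,
        n_strata=len(strata_obs),
    )


def _is_flat(loglik: np.ndarray, tol: float = 1e-8) -> bool:
    return float(np.ptp(loglik)) <= tol


def lrt_theta_difference(
    strata_a: Mapping[StratumKey, Sequence[GroupObservation]],
    strata_b: Mapping[StratumKey, Sequence[GroupObservation]],
    grid: GridSpec | None = None,
    positive_constraints: bool = False,
):
    """Likelihood-ratio test that two disjoint strata partitions share theta.

    H0: one theta maximizes the summed profile of both partitions; H1: each
    partition has its own theta. Because the partitions are disjoint strata
    sets, their log-likelihoods add, so the H0 profile is the pointwise sum
    of the two curves. The statistic 2*(max H1 - max H0) is referred to
    chi^2 with 1 df. A partition in which theta is unidentified (flat
    profile) yields p = 1 with a warning.
    """
    grid = grid or GridSpec()
    curve_a = profile_loglik(strata_a, grid, positive_constraints)
    curve_b = profile_loglik(strata_b, grid, positive_constraints)

    if _is_flat(curve_a.loglik) or _is_flat(curve_b.loglik):
        logger.warning("theta unidentified in one partition; LRT degenerate, p = 1")
        return 0.0, 1.0

    max_h1 = curve_a.max_loglik + curve_b.max_loglik
    max_h0 = float((curve_a.loglik + curve_b.loglik).max())
    statistic = max(0.0, 2.0 * (max_h1 - max_h0))
    p_value = float(stats.chi2.sf(statistic, df=1))
    return statistic, p_value
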