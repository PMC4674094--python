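import math

import numpy as np
import pytest

from ddref_lq.data_model import StratumKey, stratify_observations
from ddref_lq.lq_profile import (
    GridSpec,
    ProfileCurve,
    RatioPoint,
    credible_interval,
    ddref_from_theta,
    effective_dose,
    estimate_ddref,
    fit_stratum_at_theta,
    lrt_theta_difference,
    profile_loglik,
)
from ddref_lq.synthetic_data import default_config, simulate_group_table
from ddref_lq.validation import contradiction_strata, flat_strata, make_observation

KEY = StratumKey("B6CF1", "F", "100")


def obs_from_xy(points, weights=None, doses=None, fractions=None):
    """Observations with exactly specified (x=dose, y) pairs, unit fractions."""
    weights = weights or [1.0] * len(points)
    out = []
    for j, ((d, y), w) in enumerate(zip(points, weights)):
        out.append(
            make_observation(KEY, f"g{j}", d, 1 if fractions is None else fractions[j],
                             y=y, variance=1.0 / w)
        )
    return out


# ---------------------------------------------------------------------------
# Elementary conversions

@pytest.mark.parametrize(
    "dose,fractions,theta,expected",
    [
        (1.0, 2, 1.0, 1.5),
        (0.0, 7, 3.0, 0.0),
        (1.5, 60, 0.5, 1.51875),
    ],
)
def test_effective_dose(dose, fractions, theta, expected):
    assert effective_dose(dose, fractions, theta) == pytest.approx(expected)


@pytest.mark.parametrize(
    "theta,dose,expected",
    [(0.5, 1.0, 1.5), (0.0, 2.7, 1.0), (math.inf, 1.0, math.inf)],
)
def test_ddref_from_theta(theta, dose, expected):
    assert ddref_from_theta(theta, dose) == expected


def test_grid_covers_zero_to_infinity():
    pts = GridSpec(5).points()
    assert pts[0].ddref == 0.0 and pts[0].theta == -1.0
    assert math.isinf(pts[-1].ddref) and math.isinf(pts[-1].theta)


# ---------------------------------------------------------------------------
# Single-stratum weighted fits

def test_perfect_linear_fit():
    obs = obs_from_xy([(0, 10.0), (1, 12.0), (2, 14.0)])
    fit = fit_stratum_at_theta(obs, theta=0.0)
    assert fit.alpha == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(10.0)
    assert np.allclose(fit.residuals, 0.0, atol=1e-12)


def test_constrained_decreasing_data_collapses_to_boundary():
    obs = obs_from_xy([(0, 10.0), (1, 9.0), (2, 8.0)])
    fit = fit_stratum_at_theta(obs, theta=0.0, positive_constraints=True)
    assert fit.alpha == 0.0 and fit.constrained
    assert fit.intercept == pytest.approx(9.0)  # weighted mean
    assert float((fit.weights * fit.residuals**2).sum()) == pytest.approx(2.0)


def test_negative_theta_with_constraints_is_boundary():
    obs = obs_from_xy([(0, 10.0), (1, 12.0), (2, 14.0)])
    fit = fit_stratum_at_theta(obs, theta=-0.5, positive_constraints=True)
    assert fit.alpha == 0.0 and fit.beta == 0.0 and fit.constrained


def test_unequal_weights_match_normal_equations_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        doses = np.sort(rng.uniform(0, 1.5, size=4))
        doses[0] = 0.0
        ys = rng.uniform(1e-3, 2e-3, size=4)
        ws = rng.uniform(0.5, 5.0, size=4)
        theta = rng.uniform(-0.5, 3.0)
        obs = obs_from_xy(list(zip(doses, ys)), weights=list(ws))
        fit = fit_stratum_at_theta(obs, theta=theta)
        # independent oracle: solve the weighted normal equations directly
        x = doses + theta * doses**2
        X = np.column_stack([np.ones(4), x])
        W = np.diag(ws)
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ ys)
        assert fit.intercept == pytest.approx(coef[0], abs=1e-10)
        assert fit.alpha == pytest.approx(coef[1], abs=1e-10)


def test_normal_equations_hold_at_every_grid_point():
    """Within each unconstrained stratum fit, sum(w e) = 0 and sum(w e x) = 0."""
    cfg = default_config(seed=11, theta_true=0.5, n_per_group=50)
    strata = stratify_observations(simulate_group_table(cfg))
    curve = profile_loglik(strata, GridSpec(21))
    for fit in curve.fits_at_argmax.values():
        assert float((fit.weights * fit.residuals).sum()) == pytest.approx(0.0, abs=1e-6)
        assert float((fit.weights * fit.residuals * fit.x).sum()) == pytest.approx(
            0.0, abs=1e-6
        )


def test_constant_covariate_raises_rank_error():
    obs = obs_from_xy([(1.0, 10.0), (1.0, 11.0), (1.0, 12.0)])
    with pytest.raises(np.linalg.LinAlgError):
        fit_stratum_at_theta(obs, theta=0.0)


def test_pure_quadratic_endpoint_uses_quadratic_covariate():
    # y rises with dose^2/fractions only
    obs = []
    for j, (d, f) in enumerate([(0.0, 1), (1.0, 1), (1.0, 4), (1.5, 1)]):
        obs.append(make_observation(KEY, f"g{j}", d, f, y=1e-3 + 5e-4 * d * d / f,
                                    variance=1.0))
    fit = fit_stratum_at_theta(obs, theta=math.inf)
    assert fit.alpha == 0.0
    assert fit.beta == pytest.approx(5e-4)
    assert np.allclose(fit.residuals, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# Profile likelihood

def test_dose_flat_data_gives_flat_profile():
    strata = flat_strata()
    curve = profile_loglik(strata, GridSpec(101))
    assert float(np.ptp(curve.loglik)) <= 1e-8
    assert credible_interval(curve) == (0.0, math.inf)


def test_noiseless_recovery_within_one_grid_step():
    theta_true = 1.0
    obs = []
    for j, (d, f) in enumerate([(0.0, 1), (0.5, 1), (1.0, 1), (1.5, 1), (1.5, 10)]):
        x = d + theta_true * d * d / f
        obs.append(make_observation(KEY, f"g{j}", d, f, y=1e-3 + 2e-4 * x,
                                    variance=1e-12))
    grid = GridSpec(401)
    curve = profile_loglik({KEY: obs}, grid)
    # true DDREF 2 -> u = 2/3; nearest grid neighbours bracket it
    u_hat = grid.u_values()[curve.argmax_index]
    assert abs(u_hat - 2.0 / 3.0) <= 1.0 / 400.0


def test_variance_rescaling_preserves_argmax():
    cfg = default_config(seed=5, theta_true=1.0, n_per_group=100)
    strata = stratify_observations(simulate_group_table(cfg))
    curve = profile_loglik(strata, GridSpec(101))
    scaled = {
        k: [make_observation(o.group.stratum, o.group.group_id, o.group.total_dose,
                             o.group.fractions, y=o.y, variance=o.variance * 3.7)
            for o in v]
        for k, v in strata.items()
    }
    curve2 = profile_loglik(scaled, GridSpec(101))
    assert curve2.argmax_index == curve.argmax_index
    # pointwise ordering is preserved (monotone transform of the curve)
    assert np.array_equal(np.argsort(curve.loglik), np.argsort(curve2.loglik))


def test_estimate_invariant_to_stratum_and_group_order():
    cfg = default_config(seed=9, theta_true=0.5, n_per_group=100)
    strata = stratify_observations(simulate_group_table(cfg))
    est = estimate_ddref(strata, GridSpec(101))
    reordered = {k: list(reversed(v)) for k, v in reversed(list(strata.items()))}
    est2 = estimate_ddref(reordered, GridSpec(101))
    assert est2.point == est.point
    assert (est2.ci_low, est2.ci_high) == (est.ci_low, est.ci_high)


def test_profile_max_attains_maximum():
    cfg = default_config(seed=2, theta_true=1.0, n_per_group=100)
    strata = stratify_observations(simulate_group_table(cfg))
    curve = profile_loglik(strata, GridSpec(101))
    assert curve.max_loglik >= curve.loglik.max() - 1e-12


def test_dense_and_default_grids_agree_on_interval():
    cfg = default_config(seed=21, theta_true=1.0, n_strata=2, n_per_group=150)
    strata = stratify_observations(simulate_group_table(cfg))
    lo_d, hi_d = credible_interval(profile_loglik(strata, GridSpec(10_001)))
    lo_c, hi_c = credible_interval(profile_loglik(strata, GridSpec(401)))
    # agreement within one coarse-grid step on the u scale
    def u(d):
        return 1.0 if math.isinf(d) else d / (1.0 + d)
    assert abs(u(lo_d) - u(lo_c)) <= 1.0 / 400.0 + 1e-12
    assert abs(u(hi_d) - u(hi_c)) <= 1.0 / 400.0 + 1e-12


# ---------------------------------------------------------------------------
# Credible intervals

def test_interval_on_synthetic_parabola():
    thetas = np.linspace(-1.0, 5.0, 24001)
    grid = [RatioPoint(theta=t, ddref=1.0 + t) for t in thetas]
    loglik = -((thetas - 1.0) ** 2)
    curve = ProfileCurve(grid=grid, loglik=loglik,
                         argmax_index=int(np.argmax(loglik)), fits_at_argmax={})
    lo, hi = credible_interval(curve)
    assert lo == pytest.approx(2.0 - math.sqrt(1.92), abs=1e-3)
    assert hi == pytest.approx(2.0 + math.sqrt(1.92), abs=1e-3)


def test_boundary_case_estimates_infinite_ddref():
    strata = contradiction_strata(n_comparison=2, n_acute_only=0)
    est = estimate_ddref(strata, GridSpec(401))
    assert math.isinf(est.point)
    assert math.isinf(est.ci_high)


# ---------------------------------------------------------------------------
# Likelihood-ratio contrast

def test_lrt_identical_partitions_give_zero_statistic():
    strata_a = contradiction_strata(n_comparison=0, n_acute_only=2)
    strata_b = {
        StratumKey(k.strain + "_b", k.sex, k.age_class): v
        for k, v in contradiction_strata(n_comparison=0, n_acute_only=2).items()
    }
    stat, p = lrt_theta_difference(strata_a, strata_b, GridSpec(101))
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_lrt_flat_partition_degenerates_to_p_one():
    stat, p = lrt_theta_difference(flat_strata(1), flat_strata(2), GridSpec(51))
    assert (stat, p) == (0.0, 1.0)


def test_lrt_detects_theta_difference():
    def exact_strata(theta, tag):
        key = StratumKey(f"S{tag}", "F", "100")
        obs = []
        for j, (d, f) in enumerate([(0.0, 1), (0.5, 1), (1.0, 1), (1.5, 1), (1.5, 10)]):
            x = d + theta * d * d / f
            obs.append(make_observation(key, f"{tag}g{j}", d, f,
                                        y=1e-3 + 2e-4 * x, variance=1e-11))
        return {key: obs}

    stat, p = lrt_theta_difference(exact_strata(0.0, "a"), exact_strata(5.0, "b"),
                                   GridSpec(401))
    assert p < 0.01
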