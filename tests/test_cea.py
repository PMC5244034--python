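"""SUR estimation, ICER bootstrap, quadrant shares, CEAC and percentile CIs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depcea.cea import (
    BootstrapDistribution,
    bootstrap_cea,
    ceac,
    evaluate,
    fit_sur,
    icer,
    icer_percentile_ci,
    incremental_estimates,
    percentile_ci,
    quadrant_shares,
)


def _dist(de, dc):
    return BootstrapDistribution(np.asarray(de, float), np.asarray(dc, float),
                                 seed=None)


# -- SUR ------------------------------------------------------------------------

def test_sur_treatment_coefficients_equal_difference_in_means(rng):
    """Identical regressors in both equations: SUR == per-arm mean difference."""
    for _ in range(5):
        n = 200
        arm = rng.random(n) < 0.5
        # correlated, skewed residuals
        base = rng.gamma(1.0, 500, n)
        costs = 800 + 300 * arm + base + rng.normal(0, 200, n)
        effects = 0.7 + 0.1 * arm - base / 5000 + rng.normal(0, 0.1, n)
        res = fit_sur(costs, effects, arm.astype(float))
        dc, de = incremental_estimates(costs, effects, arm)
        assert res.delta_cost == pytest.approx(dc, abs=1e-8)
        assert res.delta_effect == pytest.approx(de, abs=1e-8)


def test_sur_residual_correlation_near_zero_for_independent_errors(rng):
    n = 50_000
    arm = (np.arange(n) % 2).astype(float)
    costs = 100 + 50 * arm + rng.normal(0, 30, n)
    effects = 0.5 + 0.1 * arm + rng.normal(0, 0.2, n)
    res = fit_sur(costs, effects, arm)
    assert abs(res.residual_correlation) < 0.015


def test_sur_degenerate_perfect_coupling():
    arm = np.array([0.0, 0, 1, 1])
    y = np.array([1.0, 2, 3, 4])
    res = fit_sur(y, y, arm)
    assert res.residual_correlation == pytest.approx(1.0)
    assert res.delta_cost == res.delta_effect


def test_sur_requires_both_arms():
    with pytest.raises(ValueError):
        fit_sur([1.0, 2.0], [0.1, 0.2], [1.0, 1.0])


# -- incremental estimates --------------------------------------------------------

def test_incremental_program_cost():
    costs = np.array([299.0, 299, 10, 10])
    arm = np.array([1.0, 1, 0, 0])
    dc, _ = incremental_estimates(costs, costs * 0, arm)
    assert dc == pytest.approx(289)


def test_incremental_estimates_toy_and_identical():
    costs = np.array([100.0, 200, 50, 150])
    eff = np.array([0.9, 0.7, 0.6, 0.8])
    arm = np.array([1.0, 1, 0, 0])
    dc, de = incremental_estimates(costs, eff, arm)
    assert dc == pytest.approx(50.0)       # 150 - 100
    assert de == pytest.approx(0.10)       # 0.8 - 0.7
    dc, de = incremental_estimates(costs, eff, np.array([1.0, 0, 1, 0]))
    assert (dc, de) == (pytest.approx(-100), pytest.approx(0.0))
    with pytest.raises(ValueError):
        incremental_estimates(costs, eff, np.zeros(4))


# -- bootstrap --------------------------------------------------------------------

def test_bootstrap_zero_variance_cohort():
    costs = np.array([500.0] * 10 + [300.0] * 10)
    eff = np.array([0.8] * 10 + [0.7] * 10)
    arm = np.array([1.0] * 10 + [0.0] * 10)
    dist = bootstrap_cea(costs, eff, arm, B=50, seed=0)
    assert np.allclose(dist.delta_costs, 200.0)
    assert np.allclose(dist.delta_effects, 0.1)


def test_bootstrap_deterministic_given_seed(rng):
    n = 60
    costs = rng.gamma(2, 300, n)
    eff = rng.normal(0.7, 0.1, n)
    arm = (np.arange(n) % 2).astype(float)
    a = bootstrap_cea(costs, eff, arm, B=100, seed=9)
    b = bootstrap_cea(costs, eff, arm, B=100, seed=9)
    np.testing.assert_array_equal(a.delta_costs, b.delta_costs)
    np.testing.assert_array_equal(a.delta_effects, b.delta_effects)
    c = bootstrap_cea(costs, eff, arm, B=100, seed=10)
    assert not np.array_equal(a.delta_costs, c.delta_costs)


def test_bootstrap_replicate_sd_matches_analytic_se(rng):
    """On a normal cohort the bootstrap SD of the effect difference matches
    the closed-form standard error of a difference in means."""
    n = 400
    arm = (np.arange(n) % 2).astype(float)
    sd = 0.2
    eff = 0.6 + 0.1 * arm + rng.normal(0, sd, n)
    costs = rng.normal(1000, 100, n)
    dist = bootstrap_cea(costs, eff, arm, B=3000, seed=3)
    ni = int(arm.sum())
    xi, xc = eff[arm == 1], eff[arm == 0]
    # bootstrap analogue uses the plug-in (ddof=0) variance within each arm
    analytic = np.sqrt(xi.var() / ni + xc.var() / (n - ni))
    assert dist.delta_effects.std() == pytest.approx(analytic, rel=0.05)


def test_bootstrap_rejects_bad_b(rng):
    with pytest.raises(ValueError):
        bootstrap_cea([1.0, 2], [0.1, 0.2], [1.0, 0], B=0)


# -- ICER ------------------------------------------------------------------------

def test_icer_arithmetic_and_undefined():
    assert round(icer(134, 0.12)) == 1117
    assert icer(0, 0.12) == 0
    assert icer(134, 0) is None


# -- quadrants ---------------------------------------------------------------------

def test_quadrant_shares_one_per_quadrant():
    dist = _dist([0.1, -0.1, 0.1, -0.1], [50, 50, -50, -50])
    assert quadrant_shares(dist) == {"NE": 0.25, "NW": 0.25,
                                     "SE": 0.25, "SW": 0.25}


def test_quadrant_dominance():
    dist = _dist([0.1, 0.2, 0.3], [-10, -20, -5])
    shares = quadrant_shares(dist)
    assert shares["SE"] == 1.0


def test_quadrant_shares_match_hand_count(rng):
    de = rng.normal(0.05, 0.1, 20)
    dc = rng.normal(10, 100, 20)
    shares = quadrant_shares(_dist(de, dc))
    hand = {
        "NE": sum(1 for e, c in zip(de, dc) if e >= 0 and c > 0) / 20,
        "NW": sum(1 for e, c in zip(de, dc) if e < 0 and c > 0) / 20,
        "SE": sum(1 for e, c in zip(de, dc) if e >= 0 and c <= 0) / 20,
        "SW": sum(1 for e, c in zip(de, dc) if e < 0 and c <= 0) / 20,
    }
    assert shares == hand
    assert sum(shares.values()) == pytest.approx(1.0)


@given(st.lists(st.tuples(st.floats(-1, 1), st.floats(-1e4, 1e4)),
                min_size=1, max_size=100))
@settings(deadline=None, max_examples=50)
def test_quadrant_shares_sum_to_one(points):
    de, dc = zip(*points)
    assert sum(quadrant_shares(_dist(de, dc)).values()) == pytest.approx(1.0)


# -- CEAC -------------------------------------------------------------------------

def test_ceac_dominant_replicate():
    curve = ceac(_dist([0.1], [-50]), [0, 1000, 1e6])
    assert np.all(curve.probabilities == 1.0)


def test_ceac_net_benefit_enumeration():
    # at λ=2000: net benefits 2000*0.1-100=100 > 0 and 2000*0.1-300=-100 < 0
    curve = ceac(_dist([0.1, 0.1], [100, 300]), [2000])
    assert curve.probabilities[0] == pytest.approx(0.5)


def test_ceac_brute_force_on_hand_replicates(rng):
    de = rng.normal(0.1, 0.2, 20)
    dc = rng.normal(100, 400, 20)
    lam = [0, 500, 20000]
    curve = ceac(_dist(de, dc), lam)
    for k, l in enumerate(lam):
        brute = np.mean([l * e - c > 0 for e, c in zip(de, dc)])
        assert curve.probabilities[k] == pytest.approx(brute)


def test_ceac_endpoint_identities(rng):
    de = rng.normal(0.05, 0.1, 500)
    dc = rng.normal(20, 300, 500)
    dist = _dist(de, dc)
    curve = ceac(dist, [0.0, 1e9])
    assert curve.probabilities[0] == pytest.approx((dc < 0).mean())
    assert curve.probabilities[1] == pytest.approx((de > 0).mean())
    with pytest.raises(ValueError):
        ceac(dist, [-1.0])


# -- percentile CIs -----------------------------------------------------------------

def test_icer_ci_contains_point_estimate_for_tight_ne_cloud(rng):
    de = rng.normal(0.1, 0.005, 2000)
    dc = rng.normal(200, 10, 2000)
    dist = _dist(de, dc)
    lo, hi = icer_percentile_ci(dist)
    point = dc.mean() / de.mean()
    assert lo < point < hi


def test_icer_ci_undefined_when_effect_brackets_zero(rng):
    de = rng.normal(0.0, 0.1, 1000)
    dc = rng.normal(100, 50, 1000)
    assert icer_percentile_ci(_dist(de, dc)) is None


def test_icer_ci_matches_hand_sorted_angles(rng):
    de = rng.uniform(0.05, 0.3, 11)
    dc = rng.uniform(-200, 400, 11)
    lo, hi = icer_percentile_ci(_dist(de, dc), alpha=0.05)
    theta = np.arctan2(dc, de)
    theta = np.where(theta < -np.pi / 2, theta + 2 * np.pi, theta)
    slopes = (dc / de)[np.argsort(theta)]
    assert lo == pytest.approx(slopes[0])    # floor(0.025*10) = 0
    assert hi == pytest.approx(slopes[10])   # ceil(0.975*10) = 10


def test_percentile_ci_brackets_mass(rng):
    x = rng.normal(0, 1, 10_000)
    lo, hi = percentile_ci(x)
    assert np.mean((x >= lo) & (x <= hi)) == pytest.approx(0.95, abs=0.01)


def test_null_arms_bootstrap_intervals_cover_zero(rng):
    """With identical arm distributions, the 95% percentile intervals for
    both incremental cost and incremental effect cover 0 in most repeats."""
    cover_c = cover_e = 0
    reps = 30
    for r in range(reps):
        n = 200
        arm = (np.arange(n) % 2).astype(float)
        costs = rng.gamma(1.2, 800, n)
        eff = rng.normal(0.75, 0.15, n)
        res = evaluate(costs, eff, arm, B=200, seed=int(rng.integers(2**31)))
        cover_c += res.ci_cost[0] <= 0 <= res.ci_cost[1]
        cover_e += res.ci_effect[0] <= 0 <= res.ci_effect[1]
    assert cover_c >= 0.8 * reps
    assert cover_e >= 0.8 * reps
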