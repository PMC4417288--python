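"""Tests of the decision machinery: regions, E(V), calibration, three actions."""

import numpy as np
import pytest
from scipy import integrate, stats

from lrfdr import (
    MixtureTheta,
    TestSummary,
    estimate_fdr,
    expected_false_discoveries,
    find_alpha,
    likelihood_ratios,
    one_sided_test,
    optimal_rule,
    outcome_counts,
    solve_cutoffs,
    two_sided_test,
)
from lrfdr.em import EMConfig, em_fit
from lrfdr.testing import _find_log_alpha

from conftest import draw_summary


def random_theta(rng, two_sided=False):
    p0 = rng.uniform(0.1, 0.9)
    if two_sided:
        p1 = (1 - p0) * rng.uniform(0.2, 0.8)
        pm1 = 1 - p0 - p1
    else:
        p1, pm1 = 1 - p0, 0.0
    return MixtureTheta(
        p0=p0,
        p1=p1,
        pm1=pm1,
        mu=rng.uniform(0.0, 4.0),
        sigma2=rng.uniform(0.05, 1.5),
        tau2=rng.uniform(0.05, 1.5),
    )


class TestSolveCutoffs:
    def test_equal_variance_closed_form(self):
        # log R linear in d: cU = (s^2/mu) ln(alpha p0/p1) + mu/2
        theta = MixtureTheta(p0=0.4, p1=0.6, mu=1.5, sigma2=0.6, tau2=0.6)
        psi, alpha = 0.8, 2.0
        region = solve_cutoffs(theta, psi, alpha, "pos")
        s2 = theta.sigma2 + psi
        expected = s2 / theta.mu * np.log(alpha * theta.p0 / theta.p1) + theta.mu / 2
        assert region.cL == -np.inf and not region.inside and not region.empty
        assert region.cU == pytest.approx(expected, rel=1e-12)

    def test_symmetric_midpoint_boundary(self):
        # equal priors, equal variances, alpha = 1: boundary halfway to mu
        theta = MixtureTheta(p0=0.5, p1=0.5, mu=2.0, sigma2=0.5, tau2=0.5)
        region = solve_cutoffs(theta, 0.5, 1.0, "pos")
        assert region.cU == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("direction", ["pos", "neg"])
    def test_roots_satisfy_ratio_equation(self, rng, direction):
        # residual check: R(c) = alpha at every finite boundary
        for _ in range(50):
            theta = random_theta(rng, two_sided=True)
            psi = rng.uniform(0.2, 3.0)
            alpha = np.exp(rng.uniform(-3, 3))
            region = solve_cutoffs(theta, psi, alpha, direction)
            for c in (region.cL, region.cU):
                if np.isfinite(c):
                    ts = TestSummary(d=np.array([c]), psi=np.array([psi]))
                    rp, rn = likelihood_ratios(ts, theta)
                    r = rp[0] if direction == "pos" else rn[0]
                    assert abs(r - alpha) <= 1e-8 * alpha

    def test_always_reject_limit(self):
        # alpha below the ratio's infimum: region is the whole line
        theta = MixtureTheta(p0=0.5, p1=0.5, mu=1.0, sigma2=0.2, tau2=0.9)
        region = solve_cutoffs(theta, 1.0, 1e-12, "pos")
        assert region.contains(np.linspace(-50, 50, 7)).all()

    def test_interval_region_when_null_is_wider(self):
        # tau2 < sigma2: the alternative is narrower, {R >= alpha} an interval
        theta = MixtureTheta(p0=0.5, p1=0.5, mu=1.0, sigma2=1.2, tau2=0.1)
        region = solve_cutoffs(theta, 0.5, 1.0, "pos")
        assert region.inside and not region.empty
        assert region.cL < 1.0 < region.cU  # contains the alternative mean


class TestOptimalRule:
    def test_rejects_at_and_above_cutoff(self):
        theta = MixtureTheta(p0=0.5, p1=0.5, mu=2.0, sigma2=0.5, tau2=0.5)
        ts = TestSummary(d=np.array([0.5, 1.0, 1.5]), psi=np.full(3, 0.5))
        ds = optimal_rule(ts, theta, alpha=1.0, direction="pos")
        # boundary at d = mu/2 = 1; ties reject
        np.testing.assert_array_equal(ds.delta, [0, 1, 1])

    def test_huge_alpha_rejects_nothing(self, rng, theta_onesided):
        ts, _ = draw_summary(theta_onesided, 500, seed=31)
        ds = optimal_rule(ts, theta_onesided, alpha=1e12, direction="pos")
        assert ds.n_discoveries == 0

    def test_matches_region_membership(self, rng):
        # dual-route check: direct thresholding vs the quadratic region solve
        for _ in range(20):
            theta = random_theta(rng)
            ts, _ = draw_summary(theta, 500, seed=int(rng.integers(1 << 31)),
                                 psi=rng.uniform(0.3, 2.0, 500))
            alpha = float(np.exp(rng.uniform(-3, 3)))
            ds = optimal_rule(ts, theta, alpha, "pos")
            member = np.array(
                [solve_cutoffs(theta, p, alpha, "pos").contains(d)
                 for d, p in zip(ts.d, ts.psi)]
            ).ravel()
            np.testing.assert_array_equal(ds.delta == 1, member)

    def test_rejection_sets_nest_in_alpha(self, rng, theta_onesided):
        ts, _ = draw_summary(theta_onesided, 2000, seed=37)
        alphas = np.logspace(2, -2, 20)  # decreasing cost: growing sets
        prev = np.zeros(2000, dtype=bool)
        for a in alphas:
            cur = optimal_rule(ts, theta_onesided, float(a), "pos").delta == 1
            assert np.all(prev <= cur)
            prev = cur


class TestExpectedFalseDiscoveries:
    def test_empty_and_full_limits(self, theta_onesided):
        ts = TestSummary(d=np.zeros(10), psi=np.ones(10))
        assert expected_false_discoveries(ts, theta_onesided, 1e15, "pos") == pytest.approx(0.0, abs=1e-12)
        full = expected_false_discoveries(ts, theta_onesided, 1e-15, "pos")
        assert full == pytest.approx(10 * theta_onesided.p0, rel=1e-10)

    def test_matches_monte_carlo_null_mass(self, rng):
        # simulate null d ~ N(0, sigma2+psi), count rejections, compare to Phi
        theta = MixtureTheta(p0=0.3, p1=0.7, mu=2.5, sigma2=0.4, tau2=0.8)
        psi, alpha, n = 1.2, 3.0, 200_000
        d0 = rng.normal(0, np.sqrt(theta.sigma2 + psi), n)
        region = solve_cutoffs(theta, psi, alpha, "pos")
        frac = region.contains(d0).mean()
        ts = TestSummary(d=np.zeros(1), psi=np.array([psi]))
        expected_frac = expected_false_discoveries(ts, theta, alpha, "pos") / theta.p0
        se = np.sqrt(expected_frac * (1 - expected_frac) / n)
        assert abs(frac - expected_frac) < 3 * se


class TestEstimateFdr:
    def test_defined_at_no_rejections(self, theta_onesided):
        # alpha = inf: empty regions, zero expected V, zero discoveries -> 0
        ts = TestSummary(d=np.zeros(5), psi=np.ones(5))
        assert estimate_fdr(ts, theta_onesided, np.inf, "pos") == 0.0
        # finite but huge alpha: E(V) is minuscule yet positive while D = 0,
        # and the guarded ratio saturates at its defined value 1
        assert estimate_fdr(ts, theta_onesided, 1e15, "pos") == 1.0

    def test_small_example_against_integration_oracle(self):
        # independent oracle: rejection region located by dense grid scan of
        # R(d), null mass by quadrature of the null density over it
        theta = MixtureTheta(p0=0.3, p1=0.7, mu=2.0, sigma2=0.4, tau2=0.9)
        d = np.array([0.5, 2.5, -1.0, 3.0, 1.8])
        psi = np.array([0.5, 0.8, 1.0, 1.3, 2.0])
        ts = TestSummary(d=d, psi=psi)
        alpha = 1.5
        ev_oracle = 0.0
        for p in psi:
            grid = np.linspace(-60, 60, 400_001)
            rp, _ = likelihood_ratios(TestSummary(d=grid, psi=np.full(grid.size, p)), theta)
            inside = rp >= alpha
            sd0 = np.sqrt(theta.sigma2 + p)
            # the region is a union of at most two tails/one interval: use the
            # boundary indices of the indicator to integrate the null density
            idx = np.flatnonzero(np.diff(inside.astype(int)))
            bounds = grid[idx]
            if inside[0] and inside[-1] and idx.size == 2:
                mass = stats.norm.cdf(bounds[0] / sd0) + stats.norm.sf(bounds[1] / sd0)
            elif idx.size == 2:
                mass = stats.norm.cdf(bounds[1] / sd0) - stats.norm.cdf(bounds[0] / sd0)
            elif idx.size == 0:
                mass = 1.0 if inside[0] else 0.0
            else:
                raise AssertionError("unexpected region shape")
            ev_oracle += theta.p0 * mass
        rp, _ = likelihood_ratios(ts, theta)
        d_count = int(np.count_nonzero(rp >= alpha))
        fdr_oracle = ev_oracle / max(d_count, ev_oracle)
        assert estimate_fdr(ts, theta, alpha, "pos") == pytest.approx(fdr_oracle, abs=1e-4)

    def test_bounded_by_one(self, rng):
        for _ in range(20):
            theta = random_theta(rng)
            ts, _ = draw_summary(theta, 200, seed=int(rng.integers(1 << 31)))
            alpha = float(np.exp(rng.uniform(-4, 4)))
            assert 0.0 <= estimate_fdr(ts, theta, alpha, "pos") <= 1.0

    def test_raw_estimator_flag(self, theta_onesided):
        ts, _ = draw_summary(theta_onesided, 1000, seed=41)
        guarded = estimate_fdr(ts, theta_onesided, 1.0, "pos", guard=True)
        raw = estimate_fdr(ts, theta_onesided, 1.0, "pos", guard=False)
        assert guarded <= 1.0
        assert raw == pytest.approx(guarded) or raw > guarded


class TestFindAlpha:
    def test_tiny_kappa_rejects_nothing(self, theta_onesided):
        ts, _ = draw_summary(theta_onesided, 500, seed=43)
        assert find_alpha(ts, theta_onesided, 1e-12 + 1e-13, "pos") == np.inf \
            or estimate_fdr(ts, theta_onesided, find_alpha(ts, theta_onesided, 1e-12 + 1e-13, "pos"), "pos") <= 1e-12 + 1e-13

    def test_boundary_optimality_vs_exhaustive_scan(self, rng, theta_onesided):
        # oracle: exhaustive scan over the sorted candidate ratios
        ts, _ = draw_summary(theta_onesided, 400, seed=47)
        kappa = 0.05
        alpha = find_alpha(ts, theta_onesided, kappa, "pos")
        rp, _ = likelihood_ratios(ts, theta_onesided)
        cands = np.unique(rp[np.isfinite(rp)])
        ok = [a for a in cands if estimate_fdr(ts, theta_onesided, float(a), "pos") <= kappa]
        assert alpha == pytest.approx(min(ok), rel=1e-12)
        below = cands[cands < alpha * (1 - 1e-12)]
        if below.size:
            assert estimate_fdr(ts, theta_onesided, float(below.max()), "pos") > kappa

    def test_level_guarantee_is_definitional(self, rng, theta_onesided):
        # rescaling every psi and recalibrating keeps FDR_hat <= kappa
        ts, _ = draw_summary(theta_onesided, 400, seed=53)
        ts2 = TestSummary(d=ts.d, psi=2 * ts.psi)
        for t in (ts, ts2):
            a = find_alpha(t, theta_onesided, 0.05, "pos")
            if np.isfinite(a):
                assert estimate_fdr(t, theta_onesided, a, "pos") <= 0.05

    def test_bisection_path_matches_exact_scan(self, theta_onesided):
        # same data through the large-N bisection and the exhaustive route
        ts, _ = draw_summary(theta_onesided, 6000, seed=59)
        la_fast = _find_log_alpha(ts, theta_onesided, 0.05, "pos")
        rp, _ = likelihood_ratios(ts, theta_onesided)
        cands = np.unique(rp[np.isfinite(rp)])
        ok = [a for a in cands if estimate_fdr(ts, theta_onesided, float(a), "pos") <= 0.05]
        assert np.exp(la_fast) == pytest.approx(min(ok), rel=1e-10)

    def test_fdr_path_monotone_up_to_discreteness(self, theta_onesided):
        # growing rejection sets: E(V) grows, D grows, and the estimate is
        # non-decreasing up to the discrete 1/D jump of the denominator
        ts, _ = draw_summary(theta_onesided, 300, seed=61)
        rp, _ = likelihood_ratios(ts, theta_onesided)
        cands = np.sort(np.unique(rp[np.isfinite(rp)]))[::-1]
        evs = np.array([expected_false_discoveries(ts, theta_onesided, float(a), "pos")
                        for a in cands])
        ds = np.array([int(np.count_nonzero(rp >= a)) for a in cands])
        fdrs = np.array([estimate_fdr(ts, theta_onesided, float(a), "pos") for a in cands])
        assert np.all(np.diff(evs) >= -1e-12)
        assert np.all(np.diff(ds) >= 0)
        assert np.all(np.diff(fdrs) >= -(1.0 / ds[1:]) - 1e-12)


class TestOneSidedTest:
    def test_composition_carries_alpha_and_fdr(self, theta_onesided):
        ts, _ = draw_summary(theta_onesided, 2000, seed=67)
        ds = one_sided_test(ts, theta_onesided, 0.05, "pos")
        assert ds.kappa == 0.05
        assert ds.fdr_hat_plus <= 0.05
        rp, _ = likelihood_ratios(ts, theta_onesided)
        np.testing.assert_array_equal(ds.delta == 1, rp >= ds.alpha_plus * (1 - 1e-12))

    def test_all_null_data_yields_few_discoveries(self, rng):
        null = MixtureTheta(p0=1.0, p1=0.0, mu=0.0, sigma2=0.3, tau2=0.5)
        ts, _ = draw_summary(null, 5000, seed=71)
        # test with a model that believes some alternatives exist
        theta = MixtureTheta(p0=0.9, p1=0.1, mu=3.0, sigma2=0.3, tau2=0.5)
        ds = one_sided_test(ts, theta, 0.05, "pos")
        assert ds.n_discoveries < 50

    def test_permutation_invariance(self, rng, theta_onesided):
        ts, _ = draw_summary(theta_onesided, 1000, seed=73, psi=rng.uniform(0.5, 2, 1000))
        perm = rng.permutation(1000)
        ds = one_sided_test(ts, theta_onesided, 0.05, "pos")
        ds_p = one_sided_test(
            TestSummary(d=ts.d[perm], psi=ts.psi[perm]), theta_onesided, 0.05, "pos"
        )
        np.testing.assert_array_equal(ds.delta[perm], ds_p.delta)


class TestTwoSidedTest:
    def test_mirror_symmetry(self, theta_twosided):
        ts, _ = draw_summary(theta_twosided, 3000, seed=79)
        mirrored = MixtureTheta(
            p0=theta_twosided.p0, p1=theta_twosided.pm1, pm1=theta_twosided.p1,
            mu=theta_twosided.mu, sigma2=theta_twosided.sigma2, tau2=theta_twosided.tau2,
        )
        ds = two_sided_test(ts, theta_twosided, 0.05, 0.05)
        ds_m = two_sided_test(
            TestSummary(d=-ts.d, psi=ts.psi), mirrored, 0.05, 0.05
        )
        np.testing.assert_array_equal(ds.delta == 1, ds_m.delta == -1)
        np.testing.assert_array_equal(ds.delta == -1, ds_m.delta == 1)

    def test_per_direction_levels_hold(self, theta_twosided):
        ts, _ = draw_summary(theta_twosided, 3000, seed=83)
        ds = two_sided_test(ts, theta_twosided, 0.05, 0.01)
        assert ds.fdr_hat_plus <= 0.05
        assert ds.fdr_hat_minus <= 0.01

    def test_degenerate_positive_component_equals_one_sided_negative(self):
        # generated with no positive effects: the three-action test and the
        # one-sided negative test make identical calls
        truth = MixtureTheta(p0=0.3, p1=0.0, pm1=0.7, mu=3.0, sigma2=0.3, tau2=0.5)
        ts, _ = draw_summary(truth, 20_000, seed=89)
        fit2 = em_fit(ts, "two_sided", cfg=EMConfig(seed=7))
        fit1 = em_fit(ts, "one_sided", "neg", cfg=EMConfig(seed=7))
        assert fit2.theta.p1 < 0.01
        ds2 = two_sided_test(ts, fit2.theta, 0.05, 0.05)
        ds1 = one_sided_test(ts, fit1.theta, 0.05, "neg")
        assert set(np.flatnonzero(ds2.delta == -1)) == set(np.flatnonzero(ds1.delta == -1))
        assert not np.any(ds2.delta == 1)


class TestOutcomeCounts:
    def test_hand_count(self):
        # 10 tests, alternatives at 0-3, rejections {0,1,2,7}
        o = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        delta = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 0])
        oc = outcome_counts(delta, o)
        assert (oc.V, oc.S, oc.D) == (1, 3, 4)
        assert oc.fdp == pytest.approx(0.25)
        assert oc.fndp == pytest.approx(1 / 6)

    def test_perfect_test(self):
        o = np.array([1, 0, -1, 0])
        oc = outcome_counts(o.copy(), o)
        assert oc.fdp == 0.0 and oc.fndp == 0.0

    def test_reject_everything_fndp_zero(self):
        o = np.array([1, 0, 1])
        oc = outcome_counts(np.ones(3, dtype=int), o)
        assert oc.fndp == 0.0  # no non-discoveries
        assert oc.fdp == pytest.approx(1 / 3)

    def test_sign_error_accounting(self):
        o = np.array([1, -1, 0])
        delta = np.array([-1, -1, 0])
        strict = outcome_counts(delta, o, sign_errors_as_false=True)
        lax = outcome_counts(delta, o, sign_errors_as_false=False)
        assert (strict.V, strict.S) == (1, 1)
        assert (lax.V, lax.S) == (0, 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            outcome_counts(np.zeros(3, dtype=int), np.zeros(4, dtype=int))
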