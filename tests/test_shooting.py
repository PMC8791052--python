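"""Desingularized shooting: launches, fates, searches, reconstruction."""

import math

import numpy as np
import pytest

from ecmwave.model import spectrum_invaded
from ecmwave.shooting import (
    Outcome,
    ShotSpec,
    closed_form_m,
    find_alpha0,
    find_alpha_for_target,
    launch_point,
    reconstruct_physical_profile,
    rhs_desingularized,
    shoot,
)


class TestRHS:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ((1.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
            ((0.0, 0.0, 0.4), (0.0, 0.0, 0.0)),
            ((0.0, 0.0, 0.9), (0.0, 0.0, 0.0)),
        ],
    )
    def test_equilibria(self, state, expected):
        assert rhs_desingularized(state, c=1.3, kappa=2.0) == pytest.approx(expected)

    def test_direct_substitution(self):
        out = rhs_desingularized((0.5, -0.1, 0.5), c=1.0, kappa=2.0)
        assert out == pytest.approx((-0.1, -0.025, 0.25))

    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError):
            rhs_desingularized((0.5, -0.1, 0.5), c=0.0, kappa=1.0)


class TestLaunchPoint:
    def test_fisher_slice_has_zero_ecm(self):
        lp = launch_point(ShotSpec(alpha=0.0, c=2.0, kappa=1.0))
        assert lp.m == 0.0
        assert 0.0 < 1.0 - lp.n <= 1e-8 * (1.0 + 1e-7)  # up to representation rounding
        assert lp.p < 0.0

    def test_expansion_values_at_given_coordinate(self):
        c, kappa, y0 = 2.0, 1.0, -45.0
        lam2, lam3 = spectrum_invaded(c, kappa).eigenvalues[1:3]
        lp = launch_point(ShotSpec(alpha=1.0, c=c, kappa=kappa, y0=y0))
        assert lp.n == pytest.approx(1.0 - math.exp(lam2 * y0), rel=1e-14)
        assert lp.p == pytest.approx(-lam2 * math.exp(lam2 * y0), rel=1e-14)
        assert lp.m == pytest.approx(math.exp(lam3 * y0), rel=1e-14)  # lam3 = 0.5

    def test_deep_launch_approaches_saddle(self):
        lp = launch_point(ShotSpec(alpha=1.0, c=1.0, kappa=1.0, y0=-80.0))
        assert lp.n == pytest.approx(1.0, abs=1e-12)
        assert lp.p == pytest.approx(0.0, abs=1e-12)
        assert lp.m == pytest.approx(0.0, abs=1e-12)

    def test_shallow_launch_rejected(self):
        with pytest.raises(ValueError, match="expansion"):
            launch_point(ShotSpec(alpha=1.0, c=2.0, kappa=1.0, y0=-1.0))


class TestShootOutcomes:
    def test_fisher_front_at_supercritical_speed(self):
        res = shoot(ShotSpec(alpha=0.0, c=2.0, kappa=1.0), max_horizon_doublings=4)
        assert res.outcome is Outcome.CONVERGES_PARTIAL
        assert res.m_inf == 0.0
        assert np.all(res.m == 0.0)

    def test_small_alpha_exits_below_two(self):
        # alpha0(1) > 0, so a tiny alpha must exit n = 0 with p < 0 there
        res = shoot(ShotSpec(alpha=1e-6, c=1.0, kappa=1.0), max_horizon_doublings=4)
        assert res.outcome is Outcome.EXITS_N_ZERO
        assert res.T is not None and res.T > 0
        assert res.p[-1] < 0.0

    def test_large_alpha_hits_degenerate_family(self):
        res = shoot(ShotSpec(alpha=1e3, c=1.0, kappa=1.0), max_horizon_doublings=8)
        assert res.outcome is Outcome.CONVERGES_DEGENERATE
        assert res.n_inf > 0.0
        assert res.m_inf == pytest.approx(1.0, abs=1e-6)

    def test_region_invariance_along_shots(self):
        # within D1: p < 0 and m strictly increasing while n in (0, 1)
        for alpha in (0.05, 0.3, 0.8):
            res = shoot(ShotSpec(alpha=alpha, c=2.0, kappa=1.0), max_horizon_doublings=4)
            inside = (res.n > 1e-7) & (res.n < 1.0 - 1e-7)
            assert np.all(res.p[inside] < 0.0)
            m_in = res.m[inside]
            assert np.all(np.diff(m_in) > 0.0)

    def test_limit_dichotomy_for_resolved_shots(self):
        # m_inf < 1 forces n_inf = 0; n_inf > 0 forces m_inf = 1
        for alpha, c in [(0.1, 2.0), (0.6, 2.0), (50.0, 1.0)]:
            res = shoot(ShotSpec(alpha=alpha, c=c, kappa=1.0), max_horizon_doublings=8)
            if res.outcome is Outcome.EXITS_N_ZERO:
                continue
            if res.m_inf < 1.0 - 1e-6:
                assert res.n_inf == pytest.approx(0.0, abs=1e-6)
            if res.n_inf > 1e-6:
                assert res.m_inf == pytest.approx(1.0, abs=1e-6)

    def test_exit_time_nondecreasing_in_alpha(self):
        alphas = [1e-6, 1e-4, 1e-2, 0.1, 0.5]
        Ts = []
        for a in alphas:
            res = shoot(ShotSpec(alpha=a, c=1.0, kappa=1.0), max_horizon_doublings=4)
            assert res.outcome is Outcome.EXITS_N_ZERO  # all below alpha0(1)
            Ts.append(res.T)
        assert all(t2 >= t1 for t1, t2 in zip(Ts, Ts[1:]))

    def test_launch_point_insensitivity(self):
        base = ShotSpec(alpha=0.3, c=2.0, kappa=1.0).resolved()
        r1 = shoot(base, max_horizon_doublings=4)
        r2 = shoot(
            ShotSpec(alpha=0.3, c=2.0, kappa=1.0, y0=base.y0 - 10.0),
            max_horizon_doublings=4,
        )
        assert abs(r1.m_inf - r2.m_inf) < 1e-6


class TestClosedFormM:
    def test_zero_tumour_gives_constant_ecm(self):
        m = closed_form_m(lambda s: 0.0, m_bar=0.3, c=1.0, kappa=1.0)
        ys = np.array([-5.0, 0.0, 5.0])
        assert np.allclose(m(ys), 0.3, atol=1e-12)

    def test_divergent_left_tail_clears_ecm(self):
        # n -> 1 to the left: the tail integral diverges and m -> 0
        n = lambda s: 1.0 / (1.0 + math.exp(min(s, 700.0)))
        m = closed_form_m(n, m_bar=0.5, c=1.0, kappa=1.0)
        assert m(-30.0) < 1e-10
        assert m(30.0) == pytest.approx(0.5, abs=1e-9)

    def test_rejects_degenerate_far_field(self):
        with pytest.raises(ValueError):
            closed_form_m(lambda s: 0.0, m_bar=1.0, c=1.0, kappa=1.0)

    def test_consistency_with_ode_along_partial_trajectory(self):
        # the m-component of a converging shot must satisfy the separable
        # closed form built from its own n-component
        res = shoot(ShotSpec(alpha=0.5, c=2.0, kappa=1.0, n_samples=20000), max_horizon_doublings=4)
        assert res.outcome is Outcome.CONVERGES_PARTIAL
        n_fn = lambda s: float(np.interp(s, res.y, res.n, left=1.0, right=0.0))
        m_fn = closed_form_m(n_fn, res.m_inf, c=2.0, kappa=1.0)
        for y in res.y[500::3000]:
            assert abs(m_fn(float(y)) - np.interp(y, res.y, res.m)) < 1e-6


class TestAlphaSearches:
    def test_alpha0_vanishes_at_supercritical_speed(self):
        lo, hi = find_alpha0(2.5, 1.0, tol_alpha=1e-6)
        assert lo == 0.0
        assert hi <= 1e-6 + 1e-12

    def test_alpha0_positive_below_two(self):
        lo, hi = find_alpha0(1.0, 1.0, tol_alpha=1e-4, alpha_hi=4.0)
        assert lo > 0.1  # strictly positive per the sub-critical theory

    def test_target_zero_ecm_returns_fisher_slice(self):
        s = find_alpha_for_target(2.0, 1.0, 0.0)
        assert s.feasible and s.alpha == 0.0

    def test_unique_alpha_for_intermediate_target(self):
        s = find_alpha_for_target(2.0, 1.0, 0.5)
        assert s.feasible
        assert 0.0 < s.alpha
        assert s.result.m_inf == pytest.approx(0.5, abs=1e-4)

    def test_far_field_level_increasing_in_alpha(self):
        alphas = np.linspace(0.05, 0.9, 8)
        m_infs = []
        for a in alphas:
            res = shoot(ShotSpec(alpha=float(a), c=2.0, kappa=1.0), max_horizon_doublings=4)
            assert res.outcome is Outcome.CONVERGES_PARTIAL
            m_infs.append(res.m_inf)
        assert all(b > a for a, b in zip(m_infs, m_infs[1:]))

    def test_sturm_oscillation_blocks_subcritical_targets(self):
        # below 2*sqrt(1 - m_bar) no orbit reaches m_bar with n > 0: every
        # probe either exits or settles strictly above the target level
        c, kappa, m_bar = 0.9, 1.0, 0.75
        for a in np.geomspace(1e-3, 50.0, 50):
            res = shoot(ShotSpec(alpha=float(a), c=c, kappa=kappa), max_horizon_doublings=4)
            if res.outcome is Outcome.EXITS_N_ZERO:
                continue
            assert res.m_inf > m_bar
        s = find_alpha_for_target(c, kappa, m_bar)
        assert not s.feasible


class TestReconstruction:
    def test_fisher_slice_is_identity_change_of_variables(self):
        res = shoot(ShotSpec(alpha=0.0, c=2.0, kappa=1.0), max_horizon_doublings=4)
        profile = reconstruct_physical_profile(res)
        # with m = 0, xi(y) = y - y_ref exactly
        assert np.allclose(np.diff(profile.xi), np.diff(res.y), atol=1e-12)
        i = np.argmin(np.abs(profile.xi))
        assert profile.N[i] == pytest.approx(0.5, abs=0.01)

    def test_xi_strictly_increasing(self):
        s = find_alpha_for_target(2.0, 1.0, 0.5)
        profile = reconstruct_physical_profile(s.result)
        assert np.all(np.diff(profile.xi) > 0.0)
        assert np.all(np.diff(profile.N) < 1e-12)
        assert np.all(np.diff(profile.M) >= 0.0)

    def test_rejects_non_wave_outcomes(self):
        res = shoot(ShotSpec(alpha=1e-6, c=1.0, kappa=1.0), max_horizon_doublings=4)
        with pytest.raises(ValueError, match="not a travelling wave"):
            reconstruct_physical_profile(res)
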