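"""Method-of-lines solver, front tracking and speed estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import coarse_speed
from ecmwave.fixtures import make_ic_variants
from ecmwave.pde import (
    FrontTrace,
    ICParams,
    PDEState,
    build_initial_condition,
    convergence_check,
    estimate_speed,
    semidiscrete_rhs,
    solve,
    track_front,
)


class TestInitialCondition:
    def test_branch_values(self):
        ic = ICParams(L=200.0, sigma=2.0, omega=1.0, M_bar=0.6)
        st_ = build_initial_condition(ic, 2001)
        x = st_.x
        # right of sigma: (N, M) = (0, M_bar)
        i = np.searchsorted(x, 2.0)
        assert st_.N[i] == 0.0 and st_.M[i] == pytest.approx(0.6)
        # at sigma - omega the bump continuously attains 1
        j = np.searchsorted(x, 1.0)
        assert st_.N[j] == pytest.approx(1.0)
        # mid-bump value exp(1 - 1/(1 - 0.25)) = e^{-1/3}
        k = np.searchsorted(x, 1.5)
        assert st_.N[k] == pytest.approx(math.exp(-1.0 / 3.0), abs=1e-12)
        assert st_.M[k] == pytest.approx(0.6 * (1.0 - st_.N[k]), abs=1e-12)
        # left of the bump: invaded, ECM cleared
        assert st_.N[0] == 1.0 and st_.M[0] == 0.0

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            ICParams(L=10.0, sigma=2.0, omega=3.0, M_bar=0.0)
        with pytest.raises(ValueError):
            ICParams(L=1.0, sigma=2.0, omega=0.5, M_bar=0.0)


class TestSemidiscreteRHS:
    @pytest.mark.parametrize("N0, M0", [(1.0, 0.0), (0.0, 0.7)])
    def test_steady_states_are_stationary(self, N0, M0):
        x = np.linspace(0.0, 10.0, 51)
        state = PDEState(x=x, N=np.full_like(x, N0), M=np.full_like(x, M0), t=0.0)
        dN, dM = semidiscrete_rhs(state, kappa=1.3)
        assert np.allclose(dN, 0.0, atol=1e-14)
        assert np.allclose(dM, 0.0, atol=1e-14)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_conservative_flux_telescoping(self, seed):
        rng = np.random.default_rng(seed)
        x = np.linspace(0.0, 5.0, 41)
        N = rng.uniform(0.0, 1.0, x.size)
        M = rng.uniform(0.0, 1.0, x.size)
        state = PDEState(x=x, N=N, M=M, t=0.0)
        dN, _ = semidiscrete_rhs(state, kappa=1.0)
        diffusion = dN - (1.0 - N) * N
        assert abs(diffusion.sum() * (x[1] - x[0])) < 1e-12

    def test_nonuniform_grid_rejected(self):
        x = np.array([0.0, 1.0, 2.5, 3.0])
        state = PDEState(x=x, N=np.zeros(4), M=np.zeros(4), t=0.0)
        with pytest.raises(ValueError, match="uniform"):
            semidiscrete_rhs(state, kappa=1.0)


class TestSolveInvariants:
    def test_bounds_and_monotone_ecm_decay(self, invasion_states_coarse):
        states = invasion_states_coarse
        for st_ in states:
            assert st_.N.min() >= 0.0
            assert st_.N.max() <= 1.0 + 1e-7  # within integrator tolerance
            assert st_.M.min() >= 0.0 and st_.M.max() <= 0.5 + 1e-12
        for a, b in zip(states, states[1:]):
            assert np.all(b.M <= a.M + 1e-12)

    def test_fisher_terminal_profile_is_monotone_front(self, fisher_states_coarse):
        final = fisher_states_coarse[-1]
        # monotone non-increasing profile (to integrator tolerance), invaded
        # behind, empty ahead
        assert np.all(np.diff(final.N) <= 1e-6)
        assert final.N[0] == pytest.approx(1.0, abs=1e-6)
        assert final.N[-1] == pytest.approx(0.0, abs=1e-6)

    def test_rejects_bad_arguments(self):
        ic = ICParams(L=10.0, sigma=2.0, omega=1.0)
        with pytest.raises(ValueError):
            solve(ic, kappa=1.0, t_end=1.0, dx=0.7)
        with pytest.raises(ValueError):
            solve(ic, kappa=1.0, t_end=-1.0, dx=0.2)


class TestFrontTracking:
    def test_linear_interpolation_exactness(self):
        x = np.linspace(0.0, 50.0, 101)  # dx = 0.5
        N = np.where(x < 37.5, 1.0, 0.0)
        ramp = (x >= 37.25) & (x <= 37.75)
        N = np.clip((37.75 - x) / 0.5, 0.0, 1.0)
        state = PDEState(x=x, N=N, M=np.zeros_like(x), t=0.0)
        trace = track_front([state])
        assert trace.positions[0] == pytest.approx(37.5, abs=1e-12)

    def test_absent_crossing_flagged(self):
        x = np.linspace(0.0, 10.0, 21)
        state = PDEState(x=x, N=np.full_like(x, 0.2), M=np.zeros_like(x), t=3.0)
        trace = track_front([state])
        assert trace.positions.size == 0
        assert trace.missing_times.tolist() == [3.0]

    def test_multiple_crossings_error(self):
        x = np.linspace(0.0, 10.0, 101)
        N = 0.55 + 0.4 * np.sin(2.0 * x)
        state = PDEState(x=x, N=N, M=np.zeros_like(x), t=0.0)
        with pytest.raises(ValueError, match="downcrossings"):
            track_front([state])

    def test_fisher_trace_is_affine_late(self, fisher_states_coarse):
        trace = track_front(fisher_states_coarse)
        est = estimate_speed(trace, window=(30.0, 60.0), dx=0.2)
        assert est.rms_residual < 0.2  # less than the grid spacing


class TestSpeedEstimate:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(c=st.floats(0.1, 3.0), x0=st.floats(0.0, 10.0))
    def test_exact_line_recovered(self, c, x0):
        t = np.linspace(50.0, 100.0, 51)
        trace = FrontTrace(times=t, positions=x0 + c * t)
        est = estimate_speed(trace)
        assert est.c_hat == pytest.approx(c, rel=1e-9)
        assert est.rms_residual < 1e-9

    def test_too_few_points_rejected(self):
        t = np.linspace(50.0, 100.0, 5)
        trace = FrontTrace(times=t, positions=3.0 + 1.5 * t)
        with pytest.raises(ValueError, match="at least 10"):
            estimate_speed(trace)


class TestConvergenceAndVariants:
    def test_single_entry_rejected(self):
        with pytest.raises(ValueError):
            convergence_check(ICParams(), 1.0, [0.2])
        with pytest.raises(ValueError):
            convergence_check(ICParams(), 1.0, [0.1, 0.2])

    def test_fisher_self_convergence(self):
        rows = convergence_check(
            ICParams(L=100.0, M_bar=0.0), 1.0, [0.2, 0.1], t_end=60.0, window=(30.0, 60.0)
        )
        assert rows[-1]["rel_diff"] < 0.01

    def test_numerical_diffusion_grows_near_maximal_ecm(self):
        kw = dict(t_end=60.0, window=(30.0, 60.0))
        rows_mid = convergence_check(ICParams(L=100.0, M_bar=0.25), 1.0, [0.4, 0.2], **kw)
        rows_high = convergence_check(ICParams(L=100.0, M_bar=0.99), 1.0, [0.4, 0.2], **kw)
        assert rows_high[-1]["rel_diff"] > rows_mid[-1]["rel_diff"]

    def test_compact_support_variants_select_same_speed(self):
        base = ICParams(L=100.0, sigma=4.0, omega=2.0, M_bar=0.25)
        variants = make_ic_variants(base, 4, seed=11, n_nodes=501)
        speeds = []
        for fx in variants:
            states = solve(fx.payload, kappa=1.0, t_end=60.0, dx=0.2)
            est = estimate_speed(track_front(states), window=(30.0, 60.0), dx=0.2)
            speeds.append(est.c_hat)
        ref = speeds[0]
        assert all(abs(s - ref) / ref < 0.02 for s in speeds[1:])
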