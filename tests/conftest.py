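"""Shared fixtures: coarse PDE runs reused across tests.

The coarse configuration (L = 120, dx = 0.2, t_end = 50) resolves front
speeds to a few percent — enough for monotonicity and agreement checks while
keeping the fastest front (speed 2) inside the domain; the acceptance tests
use the full-resolution configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecmwave.pde import ICParams, estimate_speed, solve, track_front


def coarse_speed(m_bar: float, kappa: float, L: float = 120.0, dx: float = 0.2, t_end: float = 50.0) -> float:
    ic = ICParams(L=L, M_bar=m_bar)
    states = solve(ic, kappa, t_end=t_end, dx=dx)
    trace = track_front(states)
    return estimate_speed(trace, window=(t_end / 2.0, t_end), dx=dx).c_hat


@pytest.fixture(scope="session")
def fisher_states_coarse():
    """Coarse Fisher-KPP run (M_bar = 0, kappa = 1) shared across tests."""
    return solve(ICParams(L=120.0, M_bar=0.0), kappa=1.0, t_end=50.0, dx=0.2)


@pytest.fixture(scope="session")
def invasion_states_coarse():
    """Coarse run with partial far-field ECM (M_bar = 0.5, kappa = 1)."""
    return solve(ICParams(L=120.0, M_bar=0.5), kappa=1.0, t_end=50.0, dx=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
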