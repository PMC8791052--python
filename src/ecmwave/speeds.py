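"""Characterization of the minimal invasion speed c*_kappa(m_bar).

For far-field ECM density m_bar in [0, 1) the travelling wave connecting the
invaded state to (0, m_bar) exists exactly for speeds c >= c*_kappa(m_bar).
This module bounds and locates that threshold numerically:

* ``minimal_speed``     -- nested bisection, outer on c over the analytic
  bracket [2*sqrt(1 - m_bar), 2], inner on the shooting parameter alpha;
* ``fisher_minimal_speed`` -- the scalar Fisher-KPP reduction (m identically
  zero), bisecting c on whether the alpha = 0 orbit keeps n non-negative;
* ``g_concavity_check`` -- the sign of g''(0) for the effective reaction
  g(n) = (1 - n) n (1 - M(n)) along the wave, which separates the regime
  c* = 2*sqrt(1 - m_bar) (kappa <= kappa* = (1 - m_bar)/m_bar) from the regime
  where the minimal speed exceeds it;
* ``speed_table`` / ``compare_pde_ode`` -- reconciliation of PDE-selected
  front speeds with ODE minimal speeds and of the two wave profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pde
from .model import thresholds
from .shooting import (
    Outcome,
    ShotSpec,
    UnresolvedShotError,
    find_alpha1,
    find_alpha_for_target,
    reconstruct_physical_profile,
    shoot,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MinimalSpeedResult",
    "minimal_speed",
    "fisher_minimal_speed",
    "speed_table",
    "g_concavity_check",
    "one_sided_second_derivative",
    "compare_pde_ode",
]


@dataclass
class MinimalSpeedResult:
    """Minimal wave speed estimate with its final bisection bracket."""

    c_star: float
    m_bar: float
    kappa: float
    bracket: tuple[float, float]  # (largest infeasible c, smallest feasible c)
    tol_c: float
    alpha_at_cstar: float | None


def minimal_speed(
    kappa: float,
    m_bar: float,
    tol_c: float = 1e-3,
    tol_alpha: float = 1e-8,
    tol_m: float = 1e-4,
) -> MinimalSpeedResult:
    """Locate c*_kappa(m_bar) by bisection on wave-speed feasibility.

    A speed c is feasible when the inner alpha-search finds an orbit staying
    at n > 0 and converging to (0, 0, m_bar).  The outer bisection starts from
    the analytic bracket [2*sqrt(1 - m_bar), 2]: below the lower end the
    approach to the tumour-free state is oscillatory (no non-negative wave),
    and at c = 2 a wave always exists.  m_bar = 0 is the Fisher-KPP case with
    known threshold 2 and is returned without a search.
    """
    if not kappa > 0:
        raise ValueError(f"kappa must be strictly positive, got {kappa}")
    if not 0.0 <= m_bar < 1.0:
        raise ValueError(f"m_bar must lie in [0, 1), got {m_bar}")
    if m_bar == 0.0:
        return MinimalSpeedResult(2.0, m_bar, kappa, (2.0, 2.0), tol_c, 0.0)

    lo = 2.0 * math.sqrt(1.0 - m_bar)  # infeasible side (exclusive)
    hi = 2.0

    probe_hi = find_alpha_for_target(hi, kappa, m_bar, tol_alpha=tol_alpha, tol_m=tol_m)
    if not probe_hi.feasible:
        raise RuntimeError(
            "no admissible wave found at c = 2, contradicting the existence "
            "theory; the shooting solver is misconfigured"
        )
    alpha_feasible = probe_hi.alpha

    while hi - lo > tol_c:
        mid = 0.5 * (lo + hi)
        probe = find_alpha_for_target(mid, kappa, m_bar, tol_alpha=tol_alpha, tol_m=tol_m)
        if probe.feasible:
            hi, alpha_feasible = mid, probe.alpha
        else:
            lo = mid

    return MinimalSpeedResult(
        c_star=0.5 * (lo + hi),
        m_bar=m_bar,
        kappa=kappa,
        bracket=(lo, hi),
        tol_c=tol_c,
        alpha_at_cstar=alpha_feasible,
    )


def fisher_minimal_speed(kappa: float = 1.0, tol_c: float = 0.01, c_bracket: tuple[float, float] = (1.0, 3.0)) -> float:
    """Minimal speed of the Fisher-KPP reduction (ECM identically zero).

    With alpha = 0 the ECM component of the shot vanishes identically and the
    system reduces to the classical Fisher-KPP travelling-wave ODE.  Bisection
    classifies each c by whether the orbit's n-component crosses zero; the
    threshold (analytically 2, independent of kappa) is resolved to ``tol_c``.
    """
    lo, hi = c_bracket

    def survives(c: float) -> bool:
        try:
            res = shoot(ShotSpec(alpha=0.0, c=c, kappa=kappa), max_horizon_doublings=8)
        except UnresolvedShotError:
            return True  # hovering at the horizon without crossing
        return res.outcome is not Outcome.EXITS_N_ZERO

    if survives(lo):
        return lo
    if not survives(hi):
        raise RuntimeError(f"upper bracket c={hi} not feasible; widen c_bracket")
    while hi - lo > tol_c:
        mid = 0.5 * (lo + hi)
        if survives(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def speed_table(
    kappa_list: list[float],
    m_bar_list: list[float],
    pde_config: dict | None = None,
    tol_c: float = 1e-3,
) -> pd.DataFrame:
    """PDE-selected and ODE minimal speeds over a (kappa, M_bar) sweep.

    One row per pair with columns kappa, m_bar, c_pde, c_ode and monotonicity
    flags; solver errors are recorded per cell and the sweep continues.  The
    ODE column is left NaN at M_bar = 1, where waves exist for every positive
    speed and there is no minimal one.
    """
    if not kappa_list or not m_bar_list:
        raise ValueError("kappa_list and m_bar_list must be non-empty")
    cfg = {"L": 200.0, "sigma": 2.0, "omega": 1.0, "dx": 0.1, "t_end": 100.0, "window": (50.0, 100.0)}
    if pde_config:
        cfg.update(pde_config)

    rows = []
    for kappa in kappa_list:
        for m_bar in m_bar_list:
            row: dict = {"kappa": kappa, "m_bar": m_bar, "c_pde": np.nan, "c_ode": np.nan, "error": ""}
            try:
                ic = pde.ICParams(L=cfg["L"], sigma=cfg["sigma"], omega=cfg["omega"], M_bar=m_bar)
                est = pde.run_speed(ic, kappa, t_end=cfg["t_end"], window=cfg["window"], dx=cfg["dx"])
                row["c_pde"] = est.c_hat
            except Exception as exc:  # keep sweeping
                row["error"] += f"pde: {exc}; "
            if m_bar < 1.0:
                try:
                    row["c_ode"] = minimal_speed(kappa, m_bar, tol_c=tol_c).c_star
                except Exception as exc:
                    row["error"] += f"ode: {exc}"
            rows.append(row)
    df = pd.DataFrame(rows)

    # Monotonicity flags: speed non-increasing in m_bar at fixed kappa, and
    # non-decreasing in kappa at fixed m_bar.
    df = df.sort_values(["kappa", "m_bar"]).reset_index(drop=True)
    df["decreasing_in_mbar"] = (
        df.groupby("kappa")["c_pde"].transform(lambda s: s.diff().fillna(0.0) <= 1e-12)
    )
    df["increasing_in_kappa"] = (
        df.sort_values(["m_bar", "kappa"]).groupby("m_bar")["c_pde"].transform(lambda s: s.diff().fillna(0.0) >= -1e-12)
    )
    return df


def one_sided_second_derivative(g, steps: tuple[float, ...] = (1e-2, 5e-3, 2.5e-3)) -> float:
    """g''(0) by one-sided second differences with Richardson extrapolation.

    Uses (g(2h) - 2 g(h) + g(0)) / h^2, first-order accurate one-sided (g is
    only defined for n >= 0), combined across successively halved steps to
    cancel the O(h) error terms.
    """
    vals = [(g(2.0 * h) - 2.0 * g(h) + g(0.0)) / (h * h) for h in sorted(steps, reverse=True)]
    while len(vals) > 1:
        vals = [2.0 * b - a for a, b in zip(vals, vals[1:])]
    return float(vals[0])


@dataclass
class ConcavityReport:
    """Sign check of g''(0) for the effective reaction along a wave."""

    kappa: float
    m_bar: float
    c: float
    g2_0: float
    kappa_star: float
    sub_threshold: bool  # kappa <= kappa_star(m_bar)
    concave_at_zero: bool  # g''(0) < 0
    agrees: bool
    steps: tuple[float, ...]


def g_concavity_check(
    kappa: float,
    m_bar: float,
    c: float,
    steps: tuple[float, ...] = (1e-2, 5e-3, 2.5e-3),
    tol_alpha: float = 1e-10,
) -> ConcavityReport:
    """Estimate g''(0) with g(n) = (1 - n) n (1 - M(n)) along the computed wave.

    M(n) is built parametrically from the shooting orbit (m against n), which
    is valid because n is strictly monotone along admissible waves.  g''(0) is
    estimated by one-sided second differences at the given steps, combined by
    Richardson extrapolation, since g is only defined on n >= 0.
    """
    search = find_alpha_for_target(c, kappa, m_bar, tol_alpha=tol_alpha)
    if not search.feasible:
        raise RuntimeError(f"no admissible wave at (c={c}, kappa={kappa}, m_bar={m_bar}): check not applicable")
    res = search.result

    n_traj = res.n
    m_traj = res.m
    if not np.all(np.diff(n_traj) < 0):
        keep = np.diff(n_traj, prepend=np.inf) < 0
        n_traj, m_traj = n_traj[keep], m_traj[keep]
        if n_traj.size < 10 or not np.all(np.diff(n_traj) < 0):
            raise ValueError("n is not monotone along the trajectory; cannot invert n -> y")
    # np.interp wants ascending abscissae.
    n_asc = n_traj[::-1]
    m_asc = m_traj[::-1]

    def M_of_n(nq: float) -> float:
        return float(np.interp(nq, n_asc, m_asc, left=m_asc[0], right=m_asc[-1]))

    def g(nq: float) -> float:
        return (1.0 - nq) * nq * (1.0 - M_of_n(nq))

    g2_0 = one_sided_second_derivative(g, steps)

    ks = thresholds(kappa, m_bar).kappa_star
    sub = kappa <= ks
    concave = g2_0 < 0.0
    return ConcavityReport(
        kappa=kappa,
        m_bar=m_bar,
        c=c,
        g2_0=g2_0,
        kappa_star=ks,
        sub_threshold=sub,
        concave_at_zero=concave,
        agrees=(sub == concave),
        steps=tuple(sorted(steps, reverse=True)),
    )


@dataclass
class ProfileComparison:
    """Discrepancies between PDE and ODE wave profiles aligned at N = 0.5."""

    kappa: float
    M_bar: float
    c_pde: float
    c_used: float
    sup_N: float
    sup_M: float
    l2_N: float
    l2_M: float
    retried: bool
    xi: np.ndarray
    N_pde: np.ndarray
    M_pde: np.ndarray
    N_ode: np.ndarray
    M_ode: np.ndarray


def compare_pde_ode(
    kappa: float,
    M_bar: float,
    dx: float = 0.1,
    L: float = 200.0,
    t_end: float = 100.0,
    window: tuple[float, float] = (50.0, 100.0),
    xi_range: tuple[float, float] = (-40.0, 40.0),
) -> ProfileComparison:
    """Align the late-time PDE profile with the shooting-constructed wave.

    The PDE is run from the standard initial condition, the selected speed
    c_hat is estimated, and the wave at c = c_hat is constructed by shooting
    (targeting m_bar = M_bar for M_bar < 1, the maximal-ECM wave otherwise).
    Both profiles are anchored at their N = 0.5 point and compared over
    ``xi_range`` in sup and L2 norms.  If shooting is infeasible at c_hat
    (c_hat below the minimal speed by estimation error), it is retried at
    1.02 * c_hat and flagged.
    """
    if not 0.0 <= M_bar <= 1.0:
        raise ValueError(f"M_bar must lie in [0, 1], got {M_bar}")
    ic = pde.ICParams(L=L, M_bar=M_bar)
    states = pde.solve(ic, kappa, t_end=t_end, dx=dx)
    trace = pde.track_front(states)
    est = pde.estimate_speed(trace, window=window, dx=dx)

    def construct(c: float):
        if M_bar < 1.0:
            search = find_alpha_for_target(c, kappa, M_bar)
            if not search.feasible:
                return None
            return reconstruct_physical_profile(search.result)
        return reconstruct_physical_profile(find_alpha1(c, kappa).result)

    retried = False
    c_used = est.c_hat
    profile = construct(c_used)
    if profile is None:
        retried = True
        c_used = est.c_hat * 1.02
        logger.warning("shooting infeasible at c_hat=%.4f; retrying at %.4f", est.c_hat, c_used)
        profile = construct(c_used)
        if profile is None:
            raise RuntimeError(f"shooting infeasible at c_hat={est.c_hat:.4f} and at +2%")

    final = states[-1]
    x_front = pde._locate_crossing(final.x, final.N, 0.5)
    if x_front is None:
        raise RuntimeError("final PDE profile has no N = 0.5 crossing")
    xi_pde = final.x - x_front
    mask = (xi_pde >= xi_range[0]) & (xi_pde <= xi_range[1])
    xi = xi_pde[mask]
    N_pde, M_pde = final.N[mask], final.M[mask]
    N_ode, M_ode = profile.interp(xi)

    dN = np.abs(N_pde - N_ode)
    dM = np.abs(M_pde - M_ode)
    return ProfileComparison(
        kappa=kappa,
        M_bar=M_bar,
        c_pde=est.c_hat,
        c_used=c_used,
        sup_N=float(dN.max()),
        sup_M=float(dM.max()),
        l2_N=float(np.sqrt(np.trapezoid(dN**2, xi) / (xi[-1] - xi[0]))),
        l2_M=float(np.sqrt(np.trapezoid(dM**2, xi) / (xi[-1] - xi[0]))),
        retried=retried,
        xi=xi,
        N_pde=N_pde,
        M_pde=M_pde,
        N_ode=N_ode,
        M_ode=M_ode,
    )
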