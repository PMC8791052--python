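"""Travelling waves as heteroclinic orbits of the desingularized system.

In the travelling-wave frame xi = x - c*t the model reduces to a second-order
ODE for N coupled to a first-order ODE for M, singular where M = 1 because
the diffusivity 1 - M vanishes.  The change of independent variable
dy/dxi = 1/(1 - M(xi)) removes the singularity and, writing n(y) = N, p = dn/dy,
m(y) = M, yields the regular first-order system

    n' = p
    p' = -c*p - (1 - n) * n * (1 - m)
    m' = (kappa / c) * m * (1 - m) * n.

Waves connecting the invaded state (1, 0) to a tumour-free state (0, m_bar)
are orbits leaving the saddle (1, 0, 0) along its two-dimensional unstable
manifold.  Orbits on that manifold form a one-parameter family indexed by a
shooting parameter alpha >= 0 (the coefficient of the ECM component in the
local expansion); the far-field ECM level m_inf reached as y -> +infinity is a
continuous, strictly increasing function of alpha, which makes every search in
this module a monotone bisection:

* ``find_alpha1``        -- the unique alpha whose orbit reaches (0, 0, 1),
* ``find_alpha_for_target`` -- the alpha whose orbit reaches (0, 0, m_bar),
* ``find_alpha0``        -- the infimum of alpha keeping n non-negative.

All searches are deterministic; there is no randomness anywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable

import numpy as np
from scipy.integrate import IntegrationWarning, cumulative_trapezoid, quad, solve_ivp

from .model import spectrum_invaded

__all__ = [
    "Outcome",
    "DesingState",
    "ShotSpec",
    "ShootingResult",
    "WaveProfile",
    "UnresolvedShotError",
    "rhs_desingularized",
    "launch_point",
    "shoot",
    "closed_form_m",
    "find_alpha0",
    "find_alpha1",
    "find_alpha_for_target",
    "AlphaSearchResult",
    "TargetSearchResult",
    "reconstruct_physical_profile",
]

# Integration tolerances: the shooting discrimination near critical alpha is
# exponentially sensitive, so these are deliberately tight.  The integrated
# variables are (q, p, w) = (1 - n, n', log m), so relative control acts on
# the small departing perturbation q and on m across all its decades; the
# absolute floors below are per-variable.
RTOL = 1e-11
ATOL_QP = 1e-16
ATOL_W = 1e-8

#: n at the horizon above which a converged orbit is classified as hitting the
#: non-physical family (n_bar, 0, 1).  The factor (1 - m) stalls m near 1, so
#: n is the sharper discriminator between (0, 0, 1) and (n_bar, 0, 1).
N_DEGENERATE_THRESHOLD = 1e-6

#: 1 - m at the horizon below which a converged orbit counts as having reached
#: maximal ECM density.
M_ONE_THRESHOLD = 1e-6

#: small-n floor at which integration stops and the orbit's fate is read off
#: the local linearization.  Below this level n is monotone within machine
#: resolution of the nonlinear terms, so the frozen-ECM linearization at the
#: floor decides the fate: a real-eigenvalue node with the slope p/n inside the
#: stable wedge means convergence to (0, 0, m_floor); complex eigenvalues
#: (oscillatory approach) or a slope steeper than the fast eigendirection mean
#: an imminent zero crossing.
N_FLOOR = 1e-9


class Outcome(str, Enum):
    """Fate of a shot, following the trichotomy of orbit limits."""

    EXITS_N_ZERO = "EXITS_N_ZERO"  # n crosses zero at finite y = T, p(T) < 0
    CONVERGES_PARTIAL = "CONVERGES_PARTIAL"  # -> (0, 0, m_inf), m_inf < 1
    CONVERGES_P2 = "CONVERGES_P2"  # -> (0, 0, 1)
    CONVERGES_DEGENERATE = "CONVERGES_DEGENERATE"  # -> (n_bar, 0, 1), n_bar > 0


@dataclass(frozen=True)
class DesingState:
    """A point (n, p, m) of the desingularized phase space at coordinate y."""

    y: float
    n: float
    p: float
    m: float


class UnresolvedShotError(RuntimeError):
    """Horizon reached without an n = 0 crossing or detected convergence."""

    def __init__(self, message: str, final_state: DesingState):
        super().__init__(message)
        self.final_state = final_state


#: default launch amplitude: e^{lambda2 * y0} at the launch coordinate.  The
#: leading-order expansion then carries a relative truncation error of the
#: same order, while the departing perturbation stays well above the
#: integrator's absolute error floor.
LAUNCH_AMPLITUDE = 1e-8


@dataclass(frozen=True)
class ShotSpec:
    """Configuration of a single shot from the unstable manifold of (1, 0, 0).

    ``y0`` defaults to the coordinate where e^{lambda2 * y0} equals
    ``LAUNCH_AMPLITUDE`` (pushed deeper if a large alpha would otherwise make
    the launch m-component non-small); ``y_max`` defaults to y0 + 300.
    """

    alpha: float
    c: float
    kappa: float
    y0: float | None = None
    y_max: float | None = None
    tol_converge: float = 1e-9
    n_samples: int = 2500

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"wave speed c must be strictly positive, got {self.c}")
        if not self.kappa > 0:
            raise ValueError(f"kappa must be strictly positive, got {self.kappa}")
        if self.alpha < 0:
            raise ValueError(f"shooting parameter alpha must be non-negative, got {self.alpha}")

    def resolved(self) -> "ShotSpec":
        """Fill in default y0 / y_max from the spectrum at (1, 0, 0)."""
        lam2, lam3 = spectrum_invaded(self.c, self.kappa).eigenvalues[1:3]
        if self.y0 is None:
            y0 = math.log(LAUNCH_AMPLITUDE) / lam2
            if self.alpha > 0.0:
                # Keep the launch m-component small for large alpha.
                y0 = min(y0, (math.log(1e-3) - math.log(self.alpha)) / lam3)
            if math.exp(lam2 * y0) < 1e-13:
                raise ValueError(
                    f"alpha={self.alpha} needs a launch so deep that the n-perturbation "
                    "underflows the integrator's resolution"
                )
        else:
            y0 = self.y0
        y_max = y0 + 300.0 if self.y_max is None else self.y_max
        if y_max <= y0:
            raise ValueError("y_max must exceed y0")
        return replace(self, y0=y0, y_max=y_max)


@dataclass
class ShootingResult:
    """Outcome of a shot with the detected limits and the sampled trajectory."""

    outcome: Outcome
    spec: ShotSpec
    T: float | None  # first zero of n, if finite
    n_inf: float | None
    p_inf: float | None
    m_inf: float | None
    y: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    m: np.ndarray = field(repr=False)

    @property
    def converged(self) -> bool:
        return self.outcome is not Outcome.EXITS_N_ZERO

    def final_state(self) -> DesingState:
        return DesingState(self.y[-1], self.n[-1], self.p[-1], self.m[-1])


def rhs_desingularized(state, c: float, kappa: float):
    """Right-hand side (n', p', m') of the desingularized system.

    ``state`` may be a DesingState or a length-3 sequence (n, p, m).
    """
    if c == 0:
        raise ValueError("c = 0 makes the desingularized m-equation undefined")
    if isinstance(state, DesingState):
        n, p, m = state.n, state.p, state.m
    else:
        n, p, m = state
    return (p, -c * p - (1.0 - n) * n * (1.0 - m), (kappa / c) * m * (1.0 - m) * n)


def launch_point(spec: ShotSpec) -> DesingState:
    """Leading-order unstable-manifold expansion at y0.

    (n, p, m)(y0) = (1 - e^{lam2 y0}, -lam2 e^{lam2 y0}, alpha e^{lam3 y0}),
    valid when e^{lam2 y0} <= 1e-8 so the neglected higher-order terms are
    negligible relative to the retained ones.
    """
    spec = spec.resolved()
    lam2, lam3 = spectrum_invaded(spec.c, spec.kappa).eigenvalues[1:3]
    e2 = math.exp(lam2 * spec.y0)
    if e2 > 1e-8:
        raise ValueError(
            f"launch coordinate y0={spec.y0} gives exp(lambda2*y0)={e2:.3g} > 1e-8; "
            "the truncated expansion is not justified there"
        )
    return DesingState(
        y=spec.y0,
        n=1.0 - e2,
        p=-lam2 * e2,
        m=spec.alpha * math.exp(lam3 * spec.y0),
    )


def _integrate(spec: ShotSpec):
    """One solve_ivp call over [y0, y_max] with a terminal n = 0 event.

    Internally the integrated variables are q = 1 - n and w = log(m) (plus p),
    so the integrator's relative error control acts directly on the small
    departing perturbation q ~ e^{lambda2 y} near the saddle and on m across
    the many decades it spans from its launch value alpha * e^{lambda3 y0};
    the alpha = 0 slice (m identically zero) is integrated as the reduced
    planar system.  Returns (y, n, p, m, event): the event, when n reached the
    small-n floor, is the state row (y, n, p, m) there.
    """
    # Validate launch admissibility (and spec defaults) via the public launch
    # point, then build the well-scaled initial state exactly.
    launch_point(spec)
    c, kappa = spec.c, spec.kappa
    planar = spec.alpha == 0.0
    lam2, lam3 = spectrum_invaded(c, kappa).eigenvalues[1:3]
    q0 = math.exp(lam2 * spec.y0)
    p0 = -lam2 * q0

    if planar:

        def fun(y, s):
            q, p = s
            return [-p, -c * p - q * (1.0 - q)]

        s0 = [q0, p0]
        atol = [ATOL_QP, ATOL_QP]
    else:

        def fun(y, s):
            q, p, w = s
            one_minus_m = -math.expm1(w) if w < 0.0 else 0.0
            return [
                -p,
                -c * p - q * (1.0 - q) * one_minus_m,
                (kappa / c) * one_minus_m * (1.0 - q),
            ]

        s0 = [q0, p0, math.log(spec.alpha) + lam3 * spec.y0]
        atol = [ATOL_QP, ATOL_QP, ATOL_W]

    def n_floor(y, s):
        return s[0] - (1.0 - N_FLOOR)  # q reaching 1 - floor, i.e. n reaching the floor

    n_floor.terminal = True
    n_floor.direction = 1

    t_eval = np.linspace(spec.y0, spec.y_max, spec.n_samples)
    sol = solve_ivp(
        fun,
        (spec.y0, spec.y_max),
        s0,
        method="LSODA",
        t_eval=t_eval,
        events=n_floor,
        rtol=RTOL,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failed: {sol.message}")

    y = sol.t
    n, p = 1.0 - sol.y[0], sol.y[1]
    m = np.zeros_like(n) if planar else np.exp(np.minimum(sol.y[2], 0.0))
    event = None
    if sol.status == 1:
        T = float(sol.t_events[0][0])
        se = sol.y_events[0][0]
        me = 0.0 if planar else float(math.exp(min(se[2], 0.0)))
        event = (T, 1.0 - float(se[0]), float(se[1]), me)
    return y, n, p, m, event


def _classify_at_floor(event: tuple, spec: ShotSpec) -> tuple[Outcome, float | None]:
    """Read the orbit's fate off the frozen-ECM linearization at the n-floor.

    With m frozen at its floor value the (n, p) dynamics are linear:
    n'' + c n' + (1 - m) n = 0.  Complex eigenvalues (c^2 < 4(1 - m)) mean an
    oscillatory approach, so n is about to cross zero; with real eigenvalues
    the orbit converges to (0, 0, m) unless its slope p/n lies below the fast
    eigendirection, in which case it plunges through zero.  Returns the
    outcome and, for exits, the estimated first zero T (the floor coordinate
    plus the sub-floor transit time n/|p|, negligible for plunging exits).
    """
    T_floor, n_ev, p_ev, m_ev = event
    c = spec.c
    disc = c * c - 4.0 * (1.0 - m_ev)
    if disc < 0.0:
        return Outcome.EXITS_N_ZERO, T_floor
    lam_fast = (-c - math.sqrt(disc)) / 2.0
    slope = p_ev / n_ev if n_ev > 0 else -math.inf
    if slope < lam_fast - 0.1 * (1.0 + abs(lam_fast)):
        T = T_floor + (n_ev / abs(p_ev) if p_ev < 0 else 0.0)
        return Outcome.EXITS_N_ZERO, T
    if 1.0 - m_ev <= M_ONE_THRESHOLD:
        return Outcome.CONVERGES_P2, None
    return Outcome.CONVERGES_PARTIAL, None


def shoot(spec: ShotSpec, max_horizon_doublings: int = 0) -> ShootingResult:
    """Integrate a shot and classify its fate.

    The orbit is integrated from the unstable-manifold launch point until n
    reaches a small floor (1e-10) or the horizon.  At the floor the fate is
    decided by the local linearization (see :func:`_classify_at_floor`):
    either an imminent zero crossing of n (EXITS_N_ZERO, with the first zero
    T) or convergence to the tumour-free state (0, 0, m), whose ECM level is
    read there — the residual drift of m past the floor is O(1e-10).  If the
    floor is never reached, convergence to the family (n_bar, 0, 1) is
    declared when |p| at the horizon and the drift of m over the trailing 10%
    of the horizon both fall below ``tol_converge``.  Otherwise the horizon is
    doubled up to ``max_horizon_doublings`` times (the approach to (0, 0, 1)
    along the critical orbit is algebraic, ~ c/y, not exponential); after that
    an :class:`UnresolvedShotError` is raised carrying the final state.
    """
    spec = spec.resolved()
    for _ in range(max_horizon_doublings + 1):
        y, n, p, m, event = _integrate(spec)

        if event is not None:  # n reached the floor
            T_floor, ne, pe, me = event
            y = np.append(y, T_floor)
            n = np.append(n, ne)
            p = np.append(p, pe)
            m = np.append(m, me)
            outcome, T = _classify_at_floor(event, spec)
            if outcome is Outcome.EXITS_N_ZERO:
                return ShootingResult(
                    outcome=outcome, spec=spec, T=T,
                    n_inf=None, p_inf=None, m_inf=None,
                    y=y, n=n, p=p, m=m,
                )
            return ShootingResult(
                outcome=outcome, spec=spec, T=None,
                n_inf=0.0, p_inf=0.0, m_inf=float(me),
                y=y, n=n, p=p, m=m,
            )

        # No floor crossing: test for convergence to (n_bar, 0, 1) at the horizon.
        tail = y >= spec.y0 + 0.9 * (spec.y_max - spec.y0)
        m_drift = float(np.ptp(m[tail]))
        if abs(p[-1]) < spec.tol_converge and m_drift < spec.tol_converge:
            n_inf, p_inf, m_inf = float(n[-1]), float(p[-1]), float(m[-1])
            if n_inf >= N_DEGENERATE_THRESHOLD:
                outcome = Outcome.CONVERGES_DEGENERATE
            elif 1.0 - m_inf <= M_ONE_THRESHOLD:
                outcome = Outcome.CONVERGES_P2
            else:
                outcome = Outcome.CONVERGES_PARTIAL
            return ShootingResult(
                outcome=outcome, spec=spec, T=None,
                n_inf=n_inf, p_inf=p_inf, m_inf=m_inf,
                y=y, n=n, p=p, m=m,
            )

        # Extend the horizon and retry.
        spec = replace(spec, y_max=spec.y0 + 2.0 * (spec.y_max - spec.y0))

    final = DesingState(float(y[-1]), float(n[-1]), float(p[-1]), float(m[-1]))
    raise UnresolvedShotError(
        f"horizon y_max={spec.y_max:.1f} reached without an n-floor crossing or convergence "
        f"(final state n={final.n:.3g}, p={final.p:.3g}, m={final.m:.6g}); enlarge y_max",
        final,
    )


def closed_form_m(
    n_path: Callable[[float], float], m_bar: float, c: float, kappa: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Solve the m-equation along a prescribed n(y) with far-field value m_bar.

    Separating variables in m' = (kappa/c) m (1 - m) n and imposing
    m(+inf) = m_bar gives

        m(y) = [1 + ((1 - m_bar)/m_bar) * exp((kappa/c) * int_y^inf n ds)]^{-1}.

    The tail integral is evaluated by adaptive quadrature, so ``n_path`` must
    have an integrable right tail.
    """
    if not 0.0 < m_bar < 1.0:
        raise ValueError(f"m_bar must lie in (0, 1), got {m_bar}")
    ratio = (1.0 - m_bar) / m_bar

    def tail_integral(y: float) -> float:
        with warnings.catch_warnings():
            # piecewise-linear n-paths (sampled trajectories) trip quad's
            # roundoff detector at tight tolerances; its best effort is ample
            warnings.simplefilter("ignore", IntegrationWarning)
            val, _ = quad(n_path, y, np.inf, limit=800, epsabs=1e-12, epsrel=1e-12)
        return val

    def m_of_y(y):
        ys = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.array([1.0 / (1.0 + ratio * math.exp((kappa / c) * tail_integral(yi))) for yi in ys])
        return out if np.ndim(y) else float(out[0])

    return m_of_y


# ---------------------------------------------------------------------------
# Monotone bisection searches over the shooting parameter
# ---------------------------------------------------------------------------


@dataclass
class AlphaSearchResult:
    """A critical shooting-parameter value and the shot fired at it."""

    alpha: float
    bracket: tuple[float, float]
    result: ShootingResult


@dataclass
class TargetSearchResult:
    """Result of searching for the alpha whose orbit reaches (0, 0, m_bar)."""

    feasible: bool
    alpha: float | None
    bracket: tuple[float, float]
    result: ShootingResult | None
    message: str = ""


def _shot(alpha: float, c: float, kappa: float, max_doublings: int = 8, **kw) -> ShootingResult:
    return shoot(ShotSpec(alpha=alpha, c=c, kappa=kappa, **kw), max_horizon_doublings=max_doublings)


def _end_m(res: ShootingResult) -> float:
    """Monotone score of a shot: the last m value reached (at exit or limit).

    Pointwise monotonicity of orbits in alpha makes this score strictly
    increasing in alpha, whether or not the orbit exits n = 0.
    """
    return float(res.m[-1])


def find_alpha0(c: float, kappa: float, tol_alpha: float = 1e-6, alpha_hi: float = 1.0, **kw):
    """Infimum of alpha for which n never crosses zero, by bisection.

    For c >= 2 this infimum is 0 (every non-negative alpha survives); for
    0 < c < 2 it is strictly positive.  Returns (alpha0_low, alpha0_high), the
    final bracket of width <= tol_alpha, whose lower end is the reported
    estimate.
    """
    def exits(alpha: float) -> bool:
        try:
            return _shot(alpha, c, kappa, **kw).outcome is Outcome.EXITS_N_ZERO
        except UnresolvedShotError:
            # Hovering near the critical orbit at the horizon: no exit seen.
            return False

    lo = 0.0
    hi = alpha_hi
    # Make sure the upper end survives; double if not.
    for _ in range(60):
        if not exits(hi):
            break
        hi *= 2.0
    else:
        raise RuntimeError("no surviving alpha found within 60 doublings")
    # If alpha = 0+ already survives the bracket never moves up and lo stays 0.
    while hi - lo > tol_alpha:
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if exits(mid):
            lo = mid
        else:
            hi = mid
    return lo, hi


def _critical_orbit(alpha: float, c: float, kappa: float, y_span: float = 2000.0, **kw) -> ShootingResult:
    """Raw integration at an alpha already resolved to be critical.

    The orbit at alpha1 approaches (0, 0, 1) only algebraically (n ~ c/(kappa
    y), 1 - m ~ c/y), so no finite-horizon stopping rule certifies convergence;
    the search that produced ``alpha`` certifies the limit instead, and the
    result is labelled accordingly.
    """
    kw.pop("y_max", None)
    spec = ShotSpec(alpha=alpha, c=c, kappa=kappa, **kw).resolved()
    spec = replace(spec, y_max=spec.y0 + y_span)
    y, n, p, m, event = _integrate(spec)
    if event is not None:
        T_floor, ne, pe, me = event
        y = np.append(y, T_floor)
        n = np.append(n, ne)
        p = np.append(p, pe)
        m = np.append(m, me)
    return ShootingResult(
        outcome=Outcome.CONVERGES_P2, spec=spec, T=None,
        n_inf=0.0, p_inf=0.0, m_inf=1.0,
        y=y, n=n, p=p, m=m,
    )


def find_alpha1(c: float, kappa: float, tol_alpha: float = 1e-10, **kw) -> AlphaSearchResult:
    """The unique alpha whose orbit connects (1, 0, 0) to (0, 0, 1).

    Bisection driven by the monotonicity of orbits in alpha: shots that exit
    n = 0 or settle at a partial ECM level m_inf < 1 push the lower end up;
    shots absorbed by the non-physical family (n_bar, 0, 1) or reaching
    (0, 0, 1) with margin push the upper end down.  A probe too close to the
    critical value to resolve at a finite horizon is classified by which side
    of the algebraic critical path n ~ c/(kappa y) its n-component ends on.
    ``tol_alpha`` is relative.  The returned result carries the critical orbit
    integrated over a long fixed horizon.
    """

    def side(alpha: float) -> str:
        """'lower' if the orbit is below alpha1, 'upper' if above."""
        try:
            res = _shot(alpha, c, kappa, max_doublings=4, **kw)
        except UnresolvedShotError as err:
            st = err.final_state
            return "upper" if st.n >= (c / kappa) / st.y else "lower"
        if res.outcome in (Outcome.EXITS_N_ZERO, Outcome.CONVERGES_PARTIAL):
            return "lower"
        return "upper"

    lo, hi = 0.0, 1.0
    for _ in range(60):
        if side(hi) == "upper":
            break
        lo, hi = hi, hi * 2.0
    else:
        raise RuntimeError("upper bracket for alpha1 not found within 60 doublings")

    while hi - lo > tol_alpha * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if side(mid) == "lower":
            lo = mid
        else:
            hi = mid

    alpha1 = 0.5 * (lo + hi)
    crit = _critical_orbit(alpha1, c, kappa, **kw)
    return AlphaSearchResult(alpha=alpha1, bracket=(lo, hi), result=crit)


def find_alpha_for_target(
    c: float,
    kappa: float,
    m_bar: float,
    tol_alpha: float = 1e-10,
    tol_m: float = 1e-4,
    **kw,
) -> TargetSearchResult:
    """The alpha whose orbit converges to (0, 0, m_bar), or INFEASIBLE.

    ``m_bar = 0`` returns alpha = 0 exactly (the Fisher-KPP slice, where the
    ECM stays identically zero).  Otherwise bisection on the end-m score: the
    far-field ECM level is continuous and strictly increasing in alpha, so the
    unique admissible alpha, when c is at or above the minimal speed, is the
    root of m_inf(alpha) = m_bar.  Below the minimal speed every orbit with
    end-m near m_bar exits n = 0 (oscillatory approach), the bracket collapses
    without a converging shot matching m_bar, and the search reports
    infeasible.
    """
    if not 0.0 <= m_bar < 1.0:
        raise ValueError(f"m_bar must lie in [0, 1), got {m_bar}")
    if m_bar == 0.0:
        res = _shot(0.0, c, kappa, **kw)
        feasible = res.outcome is Outcome.CONVERGES_PARTIAL and abs(res.m_inf) <= tol_m
        return TargetSearchResult(feasible=feasible, alpha=0.0, bracket=(0.0, 0.0), result=res)

    def probe_end_m(alpha: float) -> tuple[float, ShootingResult | None]:
        """End-m score of a probe; unresolvable probes score by their final m."""
        try:
            res = _shot(alpha, c, kappa, **kw)
        except UnresolvedShotError as err:
            return err.final_state.m, None
        return _end_m(res), res

    lo, hi = 0.0, 1.0
    for _ in range(60):
        score_hi, _res = probe_end_m(hi)
        if score_hi > m_bar:
            break
        lo, hi = hi, hi * 2.0
    else:
        raise RuntimeError("upper bracket for the target search not found within 60 doublings")

    best: ShootingResult | None = None
    best_alpha: float | None = None
    while hi - lo > tol_alpha * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        score, res = probe_end_m(mid)
        if res is not None and res.outcome is Outcome.CONVERGES_PARTIAL and abs(res.m_inf - m_bar) <= tol_m:
            best, best_alpha = res, mid
            # Keep refining toward the exact root for a tight bracket.
        if score < m_bar:
            lo = mid
        else:
            hi = mid

    if best is None:
        # Final probe at the midpoint of the collapsed bracket.
        alpha = 0.5 * (lo + hi)
        _score, res = probe_end_m(alpha)
        if res is not None and res.outcome is Outcome.CONVERGES_PARTIAL and abs(res.m_inf - m_bar) <= tol_m:
            best, best_alpha = res, alpha

    if best is None:
        return TargetSearchResult(
            feasible=False,
            alpha=None,
            bracket=(lo, hi),
            result=None,
            message=(
                f"no admissible orbit reaching m_bar={m_bar} with n > 0 at c={c}: "
                "bracket collapsed between exiting shots and overshooting ones "
                "(c below the minimal wave speed)"
            ),
        )
    return TargetSearchResult(feasible=True, alpha=best_alpha, bracket=(lo, hi), result=best)


# ---------------------------------------------------------------------------
# Mapping back to physical travelling-wave profiles
# ---------------------------------------------------------------------------


@dataclass
class WaveProfile:
    """A physical travelling-wave profile (N, M)(xi), anchored at N = 0.5.

    xi = x - c*t is recovered from the desingularized coordinate by
    integrating dxi/dy = 1 - m along the orbit.
    """

    xi: np.ndarray
    N: np.ndarray
    M: np.ndarray
    c: float
    m_bar: float

    def interp(self, xi_query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate (N, M) at arbitrary xi, clamping to the end states."""
        Nq = np.interp(xi_query, self.xi, self.N, left=self.N[0], right=self.N[-1])
        Mq = np.interp(xi_query, self.xi, self.M, left=self.M[0], right=self.M[-1])
        return Nq, Mq


def reconstruct_physical_profile(result: ShootingResult) -> WaveProfile:
    """Undo the desingularization: xi(y) = integral of (1 - m) dy.

    Only orbits converging to a tumour-free state map back to travelling
    waves; shots that exit n = 0 or hit the family (n_bar, 0, 1) are rejected.
    The profile is translated so that N = 0.5 at xi = 0.
    """
    if result.outcome not in (Outcome.CONVERGES_PARTIAL, Outcome.CONVERGES_P2):
        raise ValueError(f"outcome {result.outcome.value} is not a travelling wave")
    xi = cumulative_trapezoid(1.0 - result.m, result.y, initial=0.0)
    # Anchor: locate the downcrossing of N = 0.5 by linear interpolation.
    n = result.n
    idx = np.nonzero((n[:-1] >= 0.5) & (n[1:] < 0.5))[0]
    if idx.size == 0:
        raise ValueError("profile never crosses N = 0.5; cannot anchor")
    i = idx[0]
    frac = (n[i] - 0.5) / (n[i] - n[i + 1])
    xi0 = xi[i] + frac * (xi[i + 1] - xi[i])
    return WaveProfile(
        xi=xi - xi0,
        N=n.copy(),
        M=result.m.copy(),
        c=result.spec.c,
        m_bar=float(result.m_inf),
    )
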