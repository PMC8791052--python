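"""Model parameters, steady states, equilibrium spectra and analytic thresholds.

The model describes a tumour cell density N(x, t) invading an immobile
extracellular matrix (ECM) of density M(x, t).  In dimensionless form the
dynamics are

    dN/dt = d/dx[(1 - M) dN/dx] + (1 - N) N,      dM/dt = -kappa * M * N,

with a single dimensionless parameter ``kappa``, the rescaled per-cell ECM
degradation rate.  Tumour diffusivity ``1 - M`` vanishes at maximal ECM
density, so the system is a degenerate parabolic problem with cross-dependent
diffusion.

Everything downstream (PDE simulation, travelling-wave shooting, minimal-speed
searches) consumes the quantities defined here: the spatially homogeneous
steady states, the linear spectra at the two equilibria that anchor the
heteroclinic connections, and the closed-form thresholds

    kappa_star(m_bar) = (1 - m_bar) / m_bar,   m_star(kappa) = 1 / (kappa + 1),

which separate the regime where the minimal invasion speed equals the
Fisher-KPP value 2*sqrt(1 - m_bar) from the regime where it exceeds it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DimensionalParams",
    "ModelParams",
    "SteadyState",
    "SpectralInfo",
    "CriticalThresholds",
    "nondimensionalize",
    "steady_states",
    "steady_state_family",
    "desingularized_equilibria",
    "spectrum_invaded",
    "spectrum_tumour_free",
    "thresholds",
]


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional model parameters.

    Attributes
    ----------
    D_N : float
        Tumour diffusivity in ECM-free tissue (length^2 / time).
    rho : float
        Maximum tumour growth rate (1 / time).
    K : float
        Tumour carrying capacity (cells / volume).
    k : float
        Per-cell ECM degradation rate (volume / cells / time).
    M_max : float
        Maximal ECM density (mass / volume).
    """

    D_N: float
    rho: float
    K: float
    k: float
    M_max: float = 1.0

    def __post_init__(self) -> None:
        for name in ("D_N", "rho", "K", "k", "M_max"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameters: only ``kappa``, the rescaled degradation rate."""

    kappa: float

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be strictly positive, got {self.kappa}")


def nondimensionalize(p: DimensionalParams) -> ModelParams:
    """Reduce dimensional parameters to the single dimensionless group.

    kappa = (K / rho) * k compares the ECM degradation rate at carrying
    capacity against the tumour growth rate.
    """
    return ModelParams(kappa=(p.K / p.rho) * p.k)


@dataclass(frozen=True)
class SteadyState:
    """A spatially homogeneous steady state (N, M) with a descriptive label."""

    N: float
    M: float
    label: str

    _LABELS = ("trivial", "invaded", "tumour_free_max", "tumour_free_partial")

    def __post_init__(self) -> None:
        if self.label not in self._LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.N not in (0.0, 1.0):
            raise ValueError("N must be 0 or 1 at a steady state")
        if not 0.0 <= self.M <= 1.0:
            raise ValueError("M must lie in [0, 1]")


def steady_states() -> list[SteadyState]:
    """The fixed steady states: trivial, invaded and tumour-free at maximal ECM.

    The continuum of partially tumour-free states (0, M_bar), M_bar in [0, 1),
    is available through :func:`steady_state_family`.
    """
    return [
        SteadyState(0.0, 0.0, "trivial"),
        SteadyState(1.0, 0.0, "invaded"),
        SteadyState(0.0, 1.0, "tumour_free_max"),
    ]


def steady_state_family(m_bar: float) -> SteadyState:
    """Sample the tumour-free continuum (0, M_bar) at a given M_bar in [0, 1)."""
    if not 0.0 <= m_bar < 1.0:
        raise ValueError(f"M_bar must lie in [0, 1), got {m_bar}")
    return SteadyState(0.0, m_bar, "tumour_free_partial")


@dataclass(frozen=True)
class DesingEquilibrium:
    """Equilibrium of the desingularized travelling-wave system (n, p, m).

    The family (n_bar, 0, 1) with n_bar > 0 exists only after the change of
    variables removing the diffusive degeneracy; it does not correspond to a
    homogeneous state of the PDE, hence ``is_tws_limit`` is False there.
    """

    n: float
    p: float
    m: float
    is_tws_limit: bool


def desingularized_equilibria(m_bar: float | None = None, n_bar: float | None = None) -> list[DesingEquilibrium]:
    """Equilibria of the desingularized system, flagging the non-physical family.

    Returns the invaded point (1, 0, 0), a sample (0, 0, m_bar) of the
    tumour-free continuum (``m_bar`` defaults to 1, i.e. the point P2), and, if
    ``n_bar`` is given, the non-physical point (n_bar, 0, 1) flagged as not a
    travelling-wave limit.
    """
    out = [DesingEquilibrium(1.0, 0.0, 0.0, True)]
    mb = 1.0 if m_bar is None else m_bar
    if not 0.0 <= mb <= 1.0:
        raise ValueError("m_bar must lie in [0, 1]")
    out.append(DesingEquilibrium(0.0, 0.0, mb, True))
    if n_bar is not None:
        if not 0.0 < n_bar <= 1.0:
            raise ValueError("n_bar must lie in (0, 1]")
        out.append(DesingEquilibrium(n_bar, 0.0, 1.0, False))
    return out


@dataclass(frozen=True)
class SpectralInfo:
    """Eigen-data of the desingularized system linearized at an equilibrium.

    ``eigenvalues`` are ordered (lambda1, lambda2, lambda3) as printed for the
    equilibrium in question; ``eigenvectors`` matches that order (rows).
    ``mu`` is the smallest positive eigenvalue (the gap exponent controlling
    the error of the unstable-manifold expansion); ``complex_pair`` flags a
    complex-conjugate pair (spiral approach).
    """

    eigenvalues: tuple[complex, complex, complex]
    eigenvectors: tuple[np.ndarray, np.ndarray, np.ndarray]
    mu: float | None = None
    complex_pair: bool = False
    equilibrium: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))


def spectrum_invaded(c: float, kappa: float) -> SpectralInfo:
    """Spectrum at the invaded equilibrium (1, 0, 0) of the desingularized system.

    lambda1 = (-c - sqrt(c^2 + 4)) / 2 < 0 < lambda2 = (-c + sqrt(c^2 + 4)) / 2,
    lambda3 = kappa / c > 0, so (1, 0, 0) is a hyperbolic saddle with a
    two-dimensional unstable manifold: the launch pad of the shooting method.
    The in-plane eigenvectors are normalized to unit second (p) component; the
    third is the unit m-axis vector.
    """
    if not c > 0:
        raise ValueError(f"wave speed c must be strictly positive, got {c}")
    if not kappa > 0:
        raise ValueError(f"kappa must be strictly positive, got {kappa}")
    disc = math.sqrt(c * c + 4.0)
    lam1 = (-c - disc) / 2.0
    lam2 = (-c + disc) / 2.0
    lam3 = kappa / c
    # lam1 * lam2 = -1, so 1/lam1 = -lam2 and 1/lam2 = -lam1.
    v1 = np.array([-lam2, 1.0, 0.0])
    v2 = np.array([-lam1, 1.0, 0.0])
    v3 = np.array([0.0, 0.0, 1.0])
    return SpectralInfo(
        eigenvalues=(lam1, lam2, lam3),
        eigenvectors=(v1, v2, v3),
        mu=min(lam2, lam3),
        complex_pair=False,
        equilibrium=(1.0, 0.0, 0.0),
    )


def spectrum_tumour_free(c: float, m_bar1: float) -> SpectralInfo:
    """Spectrum at a tumour-free equilibrium (0, 0, m_bar1), m_bar1 in [0, 1).

    lambda_{1,2} = (-c +- sqrt(c^2 - 4(1 - m_bar1))) / 2 and lambda3 = 0: the
    point is non-hyperbolic, sitting on the centre manifold formed by the
    continuum of tumour-free states.  The pair is complex (spiral, hence no
    non-negative wave) exactly when c < 2*sqrt(1 - m_bar1).
    """
    if not c > 0:
        raise ValueError(f"wave speed c must be strictly positive, got {c}")
    if not 0.0 <= m_bar1 < 1.0:
        raise ValueError(
            f"m_bar1 must lie in [0, 1), got {m_bar1}; the degenerate family (n, 0, 1) is handled separately"
        )
    disc = c * c - 4.0 * (1.0 - m_bar1)
    complex_pair = disc < 0
    sq = np.sqrt(complex(disc))
    lam1 = (-c - sq) / 2.0
    lam2 = (-c + sq) / 2.0
    if not complex_pair:
        lam1, lam2 = lam1.real, lam2.real

    def _vec(lam: complex) -> np.ndarray:
        # (n, p) block: p = lam * n; m-component forced by kappa-row only at
        # lam = 0, which is v3.  Normalize to unit norm.
        v = np.array([1.0, lam, 0.0], dtype=complex)
        v = v / np.linalg.norm(v)
        return v if complex_pair else v.real

    v3 = np.array([0.0, 0.0, 1.0])
    return SpectralInfo(
        eigenvalues=(lam1, lam2, 0.0),
        eigenvectors=(_vec(lam1), _vec(lam2), v3),
        mu=None,
        complex_pair=complex_pair,
        equilibrium=(0.0, 0.0, m_bar1),
    )


@dataclass(frozen=True)
class CriticalThresholds:
    """Analytic thresholds framing the minimal-speed problem.

    kappa_star : threshold degradation rate (1 - m_bar) / m_bar at the given
        far-field ECM density (``inf`` for m_bar = 0, where every kappa is
        sub-threshold: the Fisher-KPP case).
    m_star : threshold far-field ECM density 1 / (kappa + 1) at the given kappa.
    c_lower : lower bound 2*sqrt(1 - m_bar) for the minimal wave speed.
    c_upper : universal upper bound 2.
    """

    kappa_star: float
    m_star: float
    c_lower: float
    c_upper: float = 2.0


def thresholds(kappa: float, m_bar: float) -> CriticalThresholds:
    """Closed-form critical values at (kappa, m_bar)."""
    if not kappa > 0:
        raise ValueError(f"kappa must be strictly positive, got {kappa}")
    if not 0.0 <= m_bar < 1.0:
        raise ValueError(f"m_bar must lie in [0, 1), got {m_bar}")
    kappa_star = math.inf if m_bar == 0.0 else (1.0 - m_bar) / m_bar
    return CriticalThresholds(
        kappa_star=kappa_star,
        m_star=1.0 / (kappa + 1.0),
        c_lower=2.0 * math.sqrt(1.0 - m_bar),
        c_upper=2.0,
    )
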