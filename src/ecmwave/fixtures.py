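"""Deterministic fixtures and figure-level reporting.

Fixtures serve two purposes: compact-support initial-condition variants used
to confirm that the selected front speed does not depend on the particular
initial profile, and a manufactured (n, m) trajectory pair that satisfies the
desingularized m-equation exactly by construction, used as a quadrature oracle.
Every fixture is reproducible bitwise from its provenance record.

``report_tables`` collects artifacts from a run directory into the CSV/JSON
bundle mirroring the figure-level outputs (front positions, speed-vs-M_bar
table, profile comparison).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .pde import ICParams, PDEState, build_initial_condition
from .shooting import closed_form_m

__all__ = ["Fixture", "make_ic_variants", "manufactured_trajectory", "report_tables"]


@dataclass
class Fixture:
    """A named, reproducible payload with its generating provenance."""

    name: str
    payload: Any
    provenance: dict
    seed: int | None = None


def make_ic_variants(base: ICParams, n_variants: int, seed: int, n_nodes: int = 2001) -> list[Fixture]:
    """Compact-support initial-condition variants.

    Variant 0 is the exact standard profile.  Subsequent variants keep compact
    support for N and M = M_bar beyond it: seeded shifts of sigma, rescalings
    of omega, and a piecewise-linear ramp profile.  All should select the same
    front speed.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    out = [
        Fixture(
            name="standard_bump",
            payload=build_initial_condition(base, n_nodes),
            provenance={"kind": "standard", "L": base.L, "sigma": base.sigma, "omega": base.omega, "M_bar": base.M_bar},
            seed=seed,
        )
    ]
    for j in range(1, n_variants):
        kind = ("shifted_sigma", "rescaled_omega", "linear_ramp")[(j - 1) % 3]
        if kind == "shifted_sigma":
            sigma = base.sigma * float(1.0 + 0.5 * rng.uniform())
            ic = ICParams(L=base.L, sigma=sigma, omega=base.omega, M_bar=base.M_bar)
            payload = build_initial_condition(ic, n_nodes)
            prov = {"kind": kind, "sigma": sigma, "omega": base.omega}
        elif kind == "rescaled_omega":
            omega = base.omega * float(0.5 + rng.uniform())
            omega = min(omega, 0.9 * base.sigma)
            ic = ICParams(L=base.L, sigma=base.sigma, omega=omega, M_bar=base.M_bar)
            payload = build_initial_condition(ic, n_nodes)
            prov = {"kind": kind, "sigma": base.sigma, "omega": omega}
        else:
            # Piecewise-linear ramp: N = 1 left of sigma - omega, linear down
            # to 0 at sigma, 0 beyond; M = M_bar * (1 - N) on the ramp.
            x = np.linspace(0.0, base.L, n_nodes)
            N = np.clip((base.sigma - x) / base.omega, 0.0, 1.0)
            M = np.where(x < base.sigma - base.omega, 0.0, base.M_bar * (1.0 - N))
            payload = PDEState(x=x, N=N, M=M, t=0.0)
            prov = {"kind": kind, "sigma": base.sigma, "omega": base.omega}
        prov.update({"L": base.L, "M_bar": base.M_bar, "variant": j})
        out.append(Fixture(name=f"variant_{j}_{kind}", payload=payload, provenance=prov, seed=seed))
    return out


def manufactured_trajectory(
    m_bar: float, c: float, kappa: float, y: np.ndarray | None = None
) -> Fixture:
    """A synthetic (n, m) pair satisfying the m-equation exactly by construction.

    n(y) = 1 / (1 + e^y) is paired with the closed-form m(y) obtained by
    integrating the separable m-equation with far-field value m_bar.  The pair
    does not satisfy the n- and p-equations; it exercises only the m-equation
    and the tail quadrature.
    """
    if not 0.0 < m_bar < 1.0:
        raise ValueError(f"m_bar must lie in (0, 1), got {m_bar}")
    if y is None:
        y = np.linspace(-20.0, 20.0, 801)

    def n_of_y(s):
        return 1.0 / (1.0 + np.exp(np.minimum(s, 700.0)))

    m_fn = closed_form_m(n_of_y, m_bar, c, kappa)
    payload = {"y": y, "n": n_of_y(y), "m": m_fn(y)}
    return Fixture(
        name=f"manufactured_mbar{m_bar}_c{c}_kappa{kappa}",
        payload=payload,
        provenance={
            "kind": "manufactured",
            "n_formula": "1/(1+exp(y))",
            "m_formula": "separable closed form with far-field m_bar",
            "m_bar": m_bar,
            "c": c,
            "kappa": kappa,
            "y_min": float(y[0]),
            "y_max": float(y[-1]),
            "n_points": int(y.size),
        },
    )


_REQUIRED = {
    "fig2": "front positions per kappa (front_trace_*.csv from `ecmwave simulate`)",
    "fig3b": "speed table (speeds.csv from `ecmwave speed-table`)",
    "fig4": "profile comparison (profile_comparison_*.csv from `ecmwave compare`)",
}


def report_tables(run_dir: str | Path, out_dir: str | Path | None = None) -> dict:
    """Collect run artifacts into the figure-level CSV/JSON bundle.

    Expects ``front_trace_*.csv`` (columns t, X), ``speeds.csv`` and
    ``profile_comparison_*.csv`` under ``run_dir``; writes
    ``fig2_front_positions.csv``, ``fig3b_speed_vs_mbar.csv``,
    ``fig4_profile_comparison.csv`` and ``summary.json``.  Missing inputs are
    reported in a single itemized error.
    """
    import pandas as pd

    run_dir = Path(run_dir)
    out_dir = run_dir if out_dir is None else Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    traces = sorted(run_dir.glob("front_trace_*.csv"))
    speeds = run_dir / "speeds.csv"
    profiles = sorted(run_dir.glob("profile_comparison_*.csv"))

    missing = []
    if not traces:
        missing.append(f"fig2: {_REQUIRED['fig2']}")
    if not speeds.exists():
        missing.append(f"fig3b: {_REQUIRED['fig3b']}")
    if not profiles:
        missing.append(f"fig4: {_REQUIRED['fig4']}")
    if missing:
        raise FileNotFoundError("missing run artifacts:\n  " + "\n  ".join(missing))

    fig2 = pd.concat(
        [pd.read_csv(f).assign(source=f.stem.removeprefix("front_trace_")) for f in traces],
        ignore_index=True,
    )
    fig2.to_csv(out_dir / "fig2_front_positions.csv", index=False)

    fig3b = pd.read_csv(speeds).sort_values(["kappa", "m_bar"])
    fig3b.to_csv(out_dir / "fig3b_speed_vs_mbar.csv", index=False)

    fig4 = pd.concat(
        [pd.read_csv(f).assign(source=f.stem.removeprefix("profile_comparison_")) for f in profiles],
        ignore_index=True,
    )
    fig4.to_csv(out_dir / "fig4_profile_comparison.csv", index=False)

    summary = {
        "n_front_traces": len(traces),
        "speed_rows": int(len(fig3b)),
        "speed_decreasing_in_mbar": bool(fig3b.get("decreasing_in_mbar", pd.Series(dtype=bool)).all()),
        "speed_increasing_in_kappa": bool(fig3b.get("increasing_in_kappa", pd.Series(dtype=bool)).all()),
        "n_profile_comparisons": len(profiles),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
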