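# Methods

This note documents the numerical methods behind `ecmwave`, the choices made
where the design was genuinely open, and what the tests do and do not
establish.

## Model and regimes

The dimensionless system couples a logistic tumour density N to an immobile
ECM density M through a degenerate cross-diffusion coefficient `1 − M` and a
mass-action degradation term `−κMN`. One parameter survives
nondimensionalization: κ = (K/ρ)k, the per-capacity degradation rate relative
to tumour growth. Waves connect the invaded state (1, 0) to a tumour-free
state (0, M̄):

* `M̄ = 0` is the Fisher–KPP reduction (the ECM never enters); fronts exist
  for all speeds c ≥ 2 and compact-support data select c = 2.
* `M̄ ∈ (0, 1)` has a strictly positive minimal speed bounded between
  `2√(1 − M̄)` (below which the tumour-free state is approached in an
  oscillatory, sign-changing way) and 2.
* `M̄ = 1` admits waves for every positive speed; the PDE nevertheless
  selects a single κ-dependent speed. The package records this selected
  value without explaining the selection principle, which remains open.

## PDE solver

Method of lines on a uniform grid over [0, L], default `L = 200`,
`dx = 0.1` (2001 nodes). The diffusion term is assembled in conservative
flux form `F_{i+1/2} = (1 − M_{i+1/2})(N_{i+1} − N_i)/dx` with arithmetic
averaging of M at half-nodes: second-order, sign-preserving (M ≤ 1), and the
discrete operator telescopes to zero over the domain, which the tests assert
to 1e-12. N gets zero-flux boundaries by setting the boundary half-node
fluxes to zero; M has no spatial operator and needs no boundary condition.
Time integration uses adaptive explicit Runge–Kutta (RK45) at
rtol 1e-8 / atol 1e-10; the diffusion stability limit, not accuracy,
dominates the step size, and the runs are bitwise reproducible. Negative
densities below 1e-6 in magnitude abort the run with a pointer to the grid
refinement check; smaller undershoots are clipped to zero post hoc with a
logged count.

The initial condition is an established tumour occupying `[0, σ − ω)`,
joined to the tumour-free far field at σ by a smooth compactly supported
bump of width ω, with `M = M̄(1 − N)` across the interface; defaults
`σ = 2, ω = 1`. Front position X(t) is the linearly interpolated downcrossing
of N = 0.5 (multiple crossings are treated as an error — they indicate a
non-monotone profile), and the speed is the least-squares slope of X(t) over
`t ∈ [50, 100]` by default, which excludes the initial transient; the rms
residual of the fit is always reported.

Grid sensitivity: numerical diffusion inflates the selected speed as M̄ → 1,
where the physical diffusivity ahead of the front vanishes. The
`convergence_check` operation estimates the speed across a decreasing
sequence of spacings and warns when the finest pair differs by more than 1%.
Tests use a coarse configuration (`L = 120, dx = 0.2, t_end = 50`), which
resolves speeds to a few percent — enough for the monotonicity and agreement
properties they assert; headline numbers use the full configuration.

## Shooting construction

Waves are heteroclinic orbits of the desingularized system
`n' = p, p' = −cp − (1 − n)n(1 − m), m' = (κ/c)m(1 − m)n`, launched from the
two-dimensional unstable manifold of the saddle (1, 0, 0) using the
leading-order expansion
`(n, p, m)(y₀) = (1 − e^{λ₂y₀}, −λ₂e^{λ₂y₀}, α e^{λ₃y₀})`.

Numerical conditioning drives three implementation choices:

* **Launch amplitude.** The launch coordinate is chosen so that
  `e^{λ₂y₀} = 1e-8`: deep enough that the neglected higher-order terms are
  O(1e-8) relative, shallow enough that the departing perturbation stays far
  above the integrator's error floor. (A much deeper launch puts the
  perturbation below double-precision resolution and the orbit never leaves
  the saddle.) For very large α the launch is pushed deeper so the
  m-component starts small; shifting y₀ by a further −10 changes the
  measured far-field ECM level by under 1e-6, which the tests assert.
* **Integrated variables.** The integrator works in `(q, p, w) =
  (1 − n, n', log m)` at rtol 1e-11 with per-variable absolute floors
  (1e-16, 1e-16, 1e-8). Relative control on q tracks the exponentially
  growing perturbation near the saddle; log m preserves relative accuracy
  over the hundreds of decades m spans from its launch value; the α = 0
  slice (m ≡ 0) is integrated as the reduced planar system.
* **Termination and fate classification.** Integration stops at a terminal
  event when n reaches a floor of 1e-9 (or at the horizon). At the floor the
  ECM level is effectively frozen (the residual drift of m past it is
  O(1e-9)), so the (n, p) dynamics are linear, `n'' + cn' + (1 − m)n = 0`,
  and the orbit's fate is read off that linearization: complex eigenvalues
  (c² < 4(1 − m)) mean an oscillatory approach and an imminent sign change
  of n (outcome EXITS_N_ZERO); with real eigenvalues the orbit converges to
  (0, 0, m) unless its slope p/n lies below the fast eigendirection by a
  margin, in which case it is plunging through zero. This classifies fates
  sharply even where the eventual sign change would occur at amplitudes far
  below machine resolution — a literal n = 0 event is unusable there because
  integrator noise dominates. Orbits that never reach the floor and whose
  p and trailing m-drift fall below 1e-9 at the horizon converge to the
  non-physical family (n̄, 0, 1) (possible only after desingularization;
  flagged as not a wave). The horizon (default 300 units past launch)
  doubles adaptively, because the approach to (0, 0, 1) along the critical
  orbit is algebraic, ~c/y, not exponential.

All critical-parameter searches are monotone bisections justified by the
pointwise monotonicity of orbits in α: α₀ (survival threshold; reported as
the lower bracket end at tolerance 1e-6), α₁ (connection to maximal ECM;
relative tolerance 1e-10), and the α matching a target far-field level m̄
(bisection on the last m value attained, which is monotone in α whether or
not the orbit exits). Probes within ~1e-10 of α₁ cannot be resolved at any
finite horizon; they are classified by which side of the algebraic path
`n ~ c/(κy)` their n-component ends on, and the orbit returned for α₁ is a
raw long-horizon integration whose limit is certified by the search rather
than by a stopping rule. On the critical orbit the decay products
`y·(1 − m) → c` and `y·(n + p/c) → c/κ` hold to ~0.2% at the default
horizon.

Physical profiles are recovered by accumulating `ξ(y) = ∫(1 − m) dy` with
the trapezoid rule and anchoring N = 0.5 at ξ = 0. For M̄ = 1 the ξ-range
grows only logarithmically in the horizon (1 − m ~ c/y), so profile
comparisons clamp the reconstructed profile to its end states beyond the
integrated range; by then n and 1 − m are O(1e-3) or smaller.

## Minimal speed and the threshold structure

`minimal_speed` bisects c over the analytic bracket `[2√(1 − m̄), 2]`
(tolerance 1e-3 by default, matching the precision at which speeds are
compared): a speed is feasible when the inner α-search finds an orbit that
keeps n > 0 and converges to (0, 0, m̄) with |m∞ − m̄| ≤ 1e-4. The lower
end is never probed (it is infeasible-by-construction in the oscillatory
regime); feasibility at c = 2 is verified and its failure treated as a
solver misconfiguration.

Two empirical regimes emerge, consistent across the PDE and ODE routes:

* κ ≤ κ*(m̄): the measured minimal speed agrees with `2√(1 − m̄)` to well
  under 1% (e.g. κ = 1, m̄ = 0.25: 1.7323 vs 1.7321).
* κ ≫ κ*(m̄): feasibility fails over a genuine interval above
  `2√(1 − m̄)` — at κ = 10, m̄ = 0.75 (30κ*) the threshold lies between
  1.20 and 1.25, matching the PDE-selected 1.22 — so the minimal speed is
  pushed strictly above the linear value, and the PDE front selects it.

A caveat the package reports honestly: at small multiples of the threshold
(κ/κ* ≲ 3, e.g. κ = 1 with m̄ ∈ {0.6, 0.75}), shooting feasibility persists
down to within ~2e-4 of `2√(1 − m̄)` — verified with an independent
high-order integration at rtol 1e-13 that keeps n > 0 to amplitudes below
1e-100 — and the PDE-selected speed is likewise indistinguishable from the
linear value at achievable grids. The pushed excess there, if nonzero, is
below the resolution of both routes; the reported positive margin at those
points is bounded by the bisection tolerance and should not be read as a
measured pushed effect.

The concavity check behind κ* builds the along-the-wave ECM profile M(n)
parametrically from a shooting orbit (valid because n is strictly monotone
along admissible waves; the phase-plane boundary-value problem is not solved
separately), forms `g(n) = (1 − n)n(1 − M(n))`, and estimates g''(0) by
one-sided second differences at steps {1e-2, 5e-3, 2.5e-3} combined by
Richardson extrapolation — one-sided because g only exists for n ≥ 0. Signs
flip as predicted across κ*: g''(0) = −0.57 at κ = 0.5κ*, +7.6 at 10κ*
(m̄ = 0.5, c = 2).

## Synthetic data and oracles

No external data exist; the study conditions are fixed by the defaults above
(L = 200, σ = 2, ω = 1, dx = 0.1, fit window [50, 100]). The fixtures module
generates (i) compact-support initial-condition variants — shifted extent,
rescaled interface width, a piecewise-linear ramp — used to confirm the
selected speed is a property of the dynamics, not the seed (agreement within
2% at the coarse grid); and (ii) a manufactured pair
`n(y) = 1/(1 + e^y)` with the matching closed-form m(y), which satisfies the
m-equation exactly by construction and exercises the tail quadrature
independently of the shooting integrator (residual under 1e-8). Seeded
variants record their single integer seed in their provenance and regenerate
bitwise identically; the solvers themselves use no randomness.

What passing tests show: internal consistency of two independent routes to
the same waves (PDE simulation vs ODE shooting; sup-norm agreement ≤ 0.05
after alignment), agreement with closed-form spectra, thresholds, decay laws
and separable solutions, and the monotonicity structure in α, κ and M̄. What
they do not show: anything about fidelity to real tumour invasion — the
model is a minimal caricature (no healthy cells, no acid field, 1D, logistic
growth, mass-action degradation).

## Known limitations

* The eventual zero crossing of a marginally oscillatory orbit can occur at
  amplitudes below the n-floor (1e-9); feasibility near a threshold is
  therefore resolved only up to a speed error that shrinks with the floor,
  estimated at a few 1e-3 in c near degenerate nodes.
* `m∞(α, c)` continuity in c is exploited only for warm-starting sweeps,
  never for correctness.
* Speeds measured from the PDE at dx = 0.1 carry a ~1% low bias for fast
  fronts and a growing high bias (numerical diffusion) as M̄ → 1; the
  convergence check quantifies, but does not remove, this.
* Sharp (corner) waves and the weak-solution formalism behind them are out
  of scope; every wave constructed here is smooth.
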