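# Methods

## Model family and assumptions

The package implements the two-state sliding-filament picture of the
actin–myosin interaction. A population of myosin-head/binding-site pairs is
indexed by the displacement `x` (nm) between the myosin-arm rest position
and the binding site; `n(x, t) ∈ [0, P]` is the probability that a pair at
`x` is attached. Attached heads act as linear springs (stiffness `k_XB`,
~2 pN/nm), so the half-filament force is `ρ_AM k_XB ∫ x n dx` and the
macroscopic active tension is proportional to the first moment of `n`.
Standing assumptions, shared by the whole model family:

* **Constant activation.** Thin-filament (calcium) regulation is frozen
  into a constant permissivity `P ∈ (0, 1]`, the fraction of binding sites
  available. `P` multiplies the attachment source term `(P − n) f`; by
  linearity this is equivalent to scaling the force output.
* **No explicit power stroke.** Heads attach pre-strained. The model
  therefore produces a single fast transient after a length step rather
  than the two experimentally resolved phases; its fast-step stiffness is
  interpreted as the stiffness of the slower (T2) curve. The `thermal`
  module makes this interpretation quantitative (below).
* **Single filament pair.** Lattice effects (one thick filament facing six
  thin filaments) are absorbed into the line density `ρ_AM` and the tension
  scale `a_XB`.

Units: lengths in nm, rates in 1/s, stresses in Pa (`a_XB` is reported in
MPa in parameter documents). Velocities are either the half-sarcomere
shortening velocity `v_hs` (nm/s, PDE level) or the normalized velocity
`v = v_hs/(SL0/2)` (1/s, moment level). Positive `v` shortens; a positive
length step `ΔL` (relative to half-sarcomere length) is a release.

## Parameters and defaults

* `SL0 = 2200 nm` (reference sarcomere length). Physiological sarcomere
  lengths span 1.7–2.3 µm; 2200 nm makes the classic skeletal maximum
  shortening velocity `v_hs ≈ 1600 nm/s` correspond to `v ≈ 1.45 1/s`.
  Configurable everywhere it enters.
* `D_M = 43 nm` (myosin-head spacing along the thick filament) normalizes
  the moments so that `μ⁰` is the fraction of binding sites engaged.
* `k_XB = 2 pN/nm`, `ρ_AM = 1 /nm` defaults for half-filament forces; the
  line density has no published value, so force-level statements are made
  on normalized or `a_XB`-scaled quantities only.
* Destruction term `q(v)`: `α√|v|` (sublinear), `α|v|` (linear),
  `α(|v|+v²)` (superlinear). The sublinear class is simulated with the
  square-root form throughout, while all force-velocity-range closed forms
  (`v_max`, `v⁰`, the normalized force–velocity curve) use the
  small-velocity linear form `α|v|`, matching the hybrid definition of the
  sublinear class (linear near rest, sublinear tail). These two conventions
  are deliberately not reconciled; the growth class only matters for the
  instantaneous-step asymptotics.
* Indicator windows (`[0, h]`, `[s₀, s₀+h]`) are closed on both ends — a
  measure-zero choice fixed for determinism.
* The printed microscopic inverse of the window model is dimensionally
  inconsistent; the package uses the roundtrip-consistent inverse
  `h = μ_f⁰ D_M / k_ATP`, `s₀ = (SL0 μ_f¹/μ_f⁰ − h)/2`.

## Closed forms and their scope

The classic steady profile at constant shortening decays for `x < 0` at
rate `g₂/v_hs`; this is the form consistent with the PDE itself and with
the closed-form force–velocity expression (which the package reproduces
from the profile to 1e−6), and is what `analytic_huxley_steady` implements.
The isometric profile is defined as the pointwise `v_hs → 0⁺` limit
(`F₁` on `(0, h)`, 0 elsewhere).

The moment reduction is exact only when `f + g` is independent of `x`
(window rates); the two-moment system is then closed without any
distributional assumption. Gaussian or higher-moment closures are out of
scope. For piecewise-constant velocity schedules the constant-velocity
solution (including the secular `t e^{−rt}` term in `μ¹`) is exact, and
the end-of-step tension is evaluated from it directly.

`characteristic_quantities` flags `v_max` as undefined (infinite, with a
warning) when `α ≥ μ_f⁰/μ_f¹`: the force–velocity curve then never crosses
zero. For the superlinear class, `k̃₂` is reported via the linear-growth
relationship `μ_f⁰/μ_f¹ + α` — the instantaneous-step limit is degenerate
(tension → 0) and the linear relationship is the standard calibration
workaround for this class, whose own tension scale consequently has no
closed-form identity.

One known self-inconsistency of the published calibration fixture: the
measured stiffness table prints `k̃₂ = 66`, but the calibrated rate
constants (`r₀ = 130` and `208 1/s` for linear and sublinear growth) are
consistent only with `k̃₂ = 65`. Tests pin the calibrated values through
the rates (equivalently `k̃₂ = 65`) and additionally check `μ_f¹`, which is
algebraically independent of `k̃₂` in both growth classes.

## Numerics

* **PDE** (`solve_h57`): operator splitting with first-order upwind
  advection along the sign of `v_hs` (CFL number 0.9, zero-inflow
  boundaries) and a pointwise-exact exponential reaction update
  `n → n_eq + (n − n_eq) e^{−(f+g)Δt}`, which removes the stiffness of the
  fast detachment branch (`g₂ ≈ 313 1/s`). Default domain `[−40, 25] nm`
  with 1300 nodes covers the exponential left tail at all tested
  velocities. Convergence is first order; the suite verifies the
  error-halving ratio under grid refinement and cross-checks the grid
  moments against the moment ODEs when `f + g` is `x`-independent.
* **Moment ODEs** (`solve_moments`): adaptive LSODA with rtol = atol =
  1e−10 by default (`r(v)` spans 1e1–1e3 1/s during step protocols);
  velocity schedules are right-continuous step functions and integration
  restarts at listed discontinuities. Instantaneous-step "limits" are
  checked numerically at `δ = 1e−9 s` with 1e−4 relative tolerance rather
  than symbolically.
* **Thermal reduction** (`thermal`): trapezoidal quadrature of Boltzmann
  averages on uniform grids truncated where the energy exceeds the minimum
  by 40 kBT; densities whose truncation retains boundary weight above
  e^{−25} are rejected. Quadrature is second order for kinked rate
  functions and spectrally accurate for smooth decaying ones; the suite
  cross-checks against rejection-sampling Monte Carlo. No concrete
  published landscape exists, so the packaged double-well landscape is a
  synthetic test article and the module's guarantees are property-based.
* **Root finding** (`huxley_vmax`): bracketed Brent iteration on the
  closed-form force–velocity curve in the reduced variable `v/φ`, xtol
  1e−14.

## Virtual experiments and synthetic data

The force–velocity protocol evaluates the steady-state tension on a
velocity grid; the quick-release protocol holds the isometric steady
state, applies a rectangular velocity pulse (`ΔL/δ` for `δ` seconds;
laboratory fast steps use `δ = 200 µs`, heartbeat-speed steps `v = 0.5
1/s`) and records the tension trace. Step sweeps default to
`ΔL ∈ [0, 0.06]` in 25 points (the experimental abscissa range is not
published; this covers the regime from near-linear drops to saturation).

A subtlety of the sublinear (√) class: the approach of the end-of-step
tension to its instantaneous asymptote is non-monotone in the step
duration at small `ΔL` (exactly evaluable from the constant-velocity
solution), so the ordering "slow ≥ fast ≥ asymptote" is asserted at every
step size for the linear class but only in the saturation regime
(`ΔL ≥ 0.015`) for the sublinear class.

The synthetic-measurement generator samples the closed-form
force–velocity curve in absolute units (50 points spanning 1.2 `v_max`,
so both the `T_iso` intercept and the zero crossing are identified) and
the normalized end-of-step curve at `δ = 200 µs`, adding i.i.d. Gaussian
noise of s.d. `sigma` on the `T/T_iso` scale (default study condition
`sigma = 0.02`); the isometric attached fraction, a microscale quantity
that tension data cannot identify, is a separate noisy observation. All
randomness flows through an explicit seed.

The recovery estimator fits the closed-form curves themselves by
nonlinear least squares — the force–velocity curve for
`(T_iso, α/r₀, (μ_f⁰/μ_f¹)/r₀)`, then the end-of-step curve for the one
remaining time scale `r₀` (step duration and growth class are part of the
protocol, hence known to the virtual experimenter). Local polynomial fits
were rejected by design: their truncation bias (~1e−3 relative at usable
window sizes) would dominate the noiseless error budget, whereas
model-form fits recover the generating values exactly when `sigma = 0`.
Because the generator and the estimator share those closed forms, the
noiseless-recovery test is an identifiability statement, not an
independent validation of the curve shapes — those are validated
separately against the ODE/PDE solvers.

What the generator does **not** emulate: correlated measurement errors,
length-dependent activation, run-to-run drift of the preparation, and the
elastic (T1) phase of real fast transients. Passing recovery tests
therefore demonstrate identifiability of the five quantities under the
model's own assumptions, not robustness to real-world systematics.

## Known limitations

* No calcium dynamics: `P` is constant per run.
* No power-stroke phase: sub-millisecond transients are outside the model
  class; spontaneous oscillations are not reproducible.
* The moment reduction requires `f + g` independent of `x`; rate families
  violating that (e.g. the classic ramp rates) are handled only at the PDE
  level.
* Moments of order ≥ 2 and Gaussian-closure variants are not provided.
* The superlinear class has no closed-form calibration; the published
  tension scale for it is not derivable from the printed relations and is
  not reproduced.
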