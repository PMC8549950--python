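# xbkin — crossbridge kinetics for cardiac active force generation

`xbkin` implements the two-state (attached/detached) sliding-filament
description of the actin–myosin interaction that underlies active force
generation in cardiac (and skeletal) muscle, for modelers who need a
subcellular force-generation component with few, experimentally
identifiable parameters — e.g. as the active-stress ingredient of
organ-level cardiac simulations.

## The model

The attached fraction `n(x, t)` of myosin-head/binding-site pairs with
displacement `x` obeys the transport equation

    ∂n/∂t − v_hs(t) ∂n/∂x = (P − n) f(x, v) − n g(x, v),

where `v_hs` is the half-sarcomere shortening velocity, `P` the
calcium-controlled permissivity, and `f`, `g` the attachment/detachment
rates. Active tension is proportional to the first moment of `n`.
The package provides:

* **`ratelib`** — the classic Huxley rates, constant-window rates, the
  velocity-dependent crossbridge-destruction term `q(v)` (sublinear
  `α√|v|`, linear `α|v|`, superlinear `α(|v|+v²)`) and microscopic ↔
  moment-level parameter conversions;
* **`h57pde`** — a first-order upwind / exact-reaction solver for the PDE,
  the classic analytic steady state and its closed-form force–velocity
  curve (oracles for everything else);
* **`moments`** — when `f + g` is independent of `x`, the exact reduction
  to two ODEs for the dimensionless moments `μ⁰, μ¹`
  (`dμ⁰/dt = −r(v)μ⁰ + Pμ_f⁰`, `dμ¹/dt = −r(v)μ¹ + Pμ_f¹ − μ⁰v`,
  `T_a = a_XB μ¹`), with closed-form steady states, constant-velocity
  solutions, end-of-step tension and instantaneous-step asymptotics;
* **`calibration`** — the closed-form inverse problem: five macroscopic
  measurements (isometric tension `T_a^iso`, attached fraction `μ⁰_iso`,
  force–velocity intercepts `v_max` and `v⁰`, fast-step stiffness `k̃₂`)
  determine the five model parameters `(r₀, α, μ_f⁰, μ_f¹, a_XB)` exactly;
* **`protocols`** — virtual force–velocity and quick-release experiments,
  Hill-1938 utilities, a seeded noisy-measurement generator and the
  matching parameter-recovery estimator;
* **`thermal`** — reduction of a soft-spin power-stroke motor to effective
  two-state rates by Boltzmann averaging over its internal degrees of
  freedom;
* **`paramio` / `cli`** — JSON parameter documents, deterministic CSV
  export and the `xbkin` command-line tool.

## Worked example

```python
import xbkin

# Macroscopic measurements for intact cardiac rat cells at room temperature
meas = xbkin.MeasuredQuantities(
    t_iso=120e3,     # isometric tension, Pa
    mu0_iso=0.22,    # isometric attached fraction
    v_max=8.0,       # zero-tension shortening velocity, 1/s
    v0=2.0,          # inverse force-velocity slope at v = 0, 1/s
    k2_tilde=65.0,   # normalized fast-step stiffness
)
m = xbkin.calibrate_linear(meas).params
print(f"r0 = {m.r0:.1f} 1/s, alpha = {m.q.alpha:.3f}, "
      f"mu_f0 = {m.mu_f0:.2f} 1/s, mu_f1 = {m.mu_f1:.4f} 1/s, "
      f"a_XB = {m.a_xb/1e6:.2f} MPa")

mu0, mu1 = xbkin.steady_moments(m, P=1.0, v=0.0)
print(f"isometric: mu0 = {mu0:.2f}, T_a = {m.a_xb*mu1/1e3:.1f} kPa")

p = xbkin.HuxleyRateParams(f1=65, g1=15, g2=313.5, h=10)
print(f"classic model: v_hs_max = {xbkin.huxley_vmax(p):.1f} nm/s "
      f"= {xbkin.huxley_vmax(p)/p.phi:.3f} phi")
```

prints

    r0 = 130.0 1/s, alpha = 24.375, mu_f0 = 28.60 1/s, mu_f1 = 0.7040 1/s, a_XB = 22.16 MPa
    isometric: mu0 = 0.22, T_a = 120.0 kPa
    classic model: v_hs_max = 1599.8 nm/s = 3.999 phi

The first line is the calibrated linear-growth parameter set (the total
detachment rate at rest, the destruction-term slope, the two attachment-rate
moments and the tension scale); the second verifies that the calibrated
model reproduces the isometric measurements it was built from; the third is
the classic skeletal-muscle maximum shortening velocity, which sits at four
times the rate scale `phi = (f1+g1)h/2`.

The same calibration from the shell:

    xbkin calibrate --growth linear --tiso-kpa 120 --mu0-iso 0.22 \
        --vmax 8 --v0 2 --k2 65

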