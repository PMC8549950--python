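"""Virtual experiments: force-velocity sweeps, quick-release length steps,
Hill-1938 utilities and a seeded synthetic-measurement generator with a
matching parameter-recovery estimator.

These protocols emulate the two classical characterizations of active
muscle: the steady force-velocity curve (isotonic release) and the tension
reached immediately after a fast length step (the T2-L2 curve), applied
either at laboratory speed (200 us steps) or at the slower shortening
velocities typical of a heartbeat (~0.5 1/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .moments import (
    MeasuredQuantities,
    MomentRateParams,
    MomentTrajectory,
    StepProtocol,
    characteristic_quantities,
    end_of_step_tension,
    isometric_state,
    normalized_force_velocity,
    solve_moments,
    steady_moments,
)
from .ratelib import GrowthKind, QSpec

__all__ = [
    "HillParams",
    "SyntheticDataset",
    "hill_tension",
    "hill_vmax",
    "normalize_fiber_velocity",
    "run_force_velocity",
    "run_length_step",
    "generate_noisy_measurements",
    "recover_measurements",
]


@dataclass(frozen=True)
class HillParams:
    """Hill hyperbola (T + a) v = b (T_iso - T) in normalized-velocity form.

    ``a_over_tiso`` is dimensionless (Hill's fit: 0.22), ``b`` a normalized
    rate (1/s) and ``t_iso`` the stall tension (Pa or any consistent unit).
    """

    a_over_tiso: float
    b: float
    t_iso: float = 1.0

    def __post_init__(self) -> None:
        if self.a_over_tiso <= 0 or self.b <= 0 or self.t_iso <= 0:
            raise ValueError("Hill parameters must be positive")


def hill_tension(v, p: HillParams):
    """Tension on the Hill hyperbola at normalized velocity ``v >= 0``.

    Solving the hyperbola for T: ``T(v) = (b T_iso - a v) / (v + b)``;
    T(0) = T_iso and T(v_max) = 0.
    """
    v = np.asarray(v, dtype=float)
    a = p.a_over_tiso * p.t_iso
    out = (p.b * p.t_iso - a * v) / (v + p.b)
    return out if out.ndim else float(out)


def hill_vmax(p: HillParams) -> float:
    """Zero-tension intercept v_max = b T_iso / a = b / (a/T_iso)."""
    return p.b / p.a_over_tiso


def normalize_fiber_velocity(b_fiber_mm_per_s: float, l_fiber_mm: float) -> float:
    """Fiber-level rate constant divided by fiber length (1/s).

    Arguments carry explicit millimetre units to rule out cm/mm mix-ups:
    Hill's b_fiber = 1.03 cm/s = 10.3 mm/s over L_fiber = 38 mm gives
    b = 0.271 1/s.
    """
    if l_fiber_mm <= 0:
        raise ValueError("fiber length must be positive")
    return b_fiber_mm_per_s / l_fiber_mm


def run_force_velocity(
    m: MomentRateParams, P: float, v_grid: np.ndarray
) -> pd.DataFrame:
    """Steady normalized tension at each velocity of ``v_grid``.

    Uses the closed-form steady state of the moment ODEs; the result is
    independent of P and a_xb (columns ``v_per_s``, ``T_over_Tiso``).
    """
    v_grid = np.asarray(v_grid, dtype=float)
    t_iso = m.a_xb * P * m.mu_f1 / m.r0
    tension = np.array(
        [m.a_xb * steady_moments(m, P, float(v))[1] for v in v_grid]
    )
    return pd.DataFrame({"v_per_s": v_grid, "T_over_Tiso": tension / t_iso})


def run_length_step(
    m: MomentRateParams,
    P: float,
    step: StepProtocol,
    t_end: float,
    n_out: int = 401,
) -> pd.DataFrame:
    """Quick-release protocol: isometric steady state, rectangular velocity
    pulse ``v = delta_l/delta_t`` on [0, delta_t], then recovery at v = 0.

    Returns columns ``t_s``, ``T_a_Pa``, ``T_over_Tiso``.  The value at
    ``t = delta_t`` matches :func:`moments.end_of_step_tension` and the
    post-step recovery towards T_iso is governed by r0.
    """
    if t_end < step.delta_t:
        raise ValueError("t_end must cover the step duration")
    init = isometric_state(m, P)
    v_bar = step.v_bar

    def v_of_t(t: float) -> float:
        return v_bar if t <= step.delta_t else 0.0

    t_eval = np.union1d(np.linspace(0.0, t_end, n_out), [step.delta_t])
    traj = solve_moments(
        m, P, v_of_t, init, t_end, t_eval=t_eval, breaks=(step.delta_t,)
    )
    t_iso = m.a_xb * init.mu1
    return pd.DataFrame(
        {
            "t_s": traj.t,
            "T_a_Pa": traj.tension,
            "T_over_Tiso": traj.tension / t_iso,
        }
    )


@dataclass
class SyntheticDataset:
    """Seeded synthetic measurements for parameter-recovery studies.

    ``fv_v`` / ``fv_tension_pa`` sample the steady force-velocity curve in
    absolute units (so the v = 0 intercept identifies T_iso);
    ``step_dl`` / ``step_tension_norm`` / ``step_dt`` sample the normalized
    end-of-step tension; ``mu0_iso_obs`` is a separate noisy observation of
    the isometric attached fraction (a microscale quantity that tension data
    cannot identify).  ``sigma`` is the noise s.d. on the T/T_iso scale.
    """

    fv_v: np.ndarray
    fv_tension_pa: np.ndarray
    step_dl: np.ndarray
    step_tension_norm: np.ndarray
    step_dt: np.ndarray
    mu0_iso_obs: float
    growth: GrowthKind
    sigma: float
    seed: int


def generate_noisy_measurements(
    m: MomentRateParams,
    P: float,
    sigma: float,
    n_points: int = 50,
    seed: int = 0,
    delta_t: float = 200e-6,
    n_steps: int = 25,
    dl_max: float = 0.06,
    v_span: float = 1.2,
) -> SyntheticDataset:
    """Simulate the two protocols and add i.i.d. Gaussian noise.

    The velocity grid spans [0, v_span * v_max] (so the zero crossing is
    bracketed) and the step sweep [0, dl_max] in ``n_steps`` points with
    duration ``delta_t`` (laboratory fast steps by default).  Deterministic
    given ``seed``; ``sigma = 0`` returns points exactly on the closed-form
    curves.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    meas = characteristic_quantities(m, P)
    if not math.isfinite(meas.v_max):
        raise ValueError("model has no finite v_max; cannot span zero crossing")
    rng = np.random.default_rng(seed)

    v = np.linspace(0.0, v_span * meas.v_max, n_points)
    fv_norm = normalized_force_velocity(m, v)
    fv_tension = meas.t_iso * (fv_norm + sigma * rng.standard_normal(n_points))

    dl = np.linspace(0.0, dl_max, n_steps)
    t_iso = m.a_xb * P * m.mu_f1 / m.r0
    step_norm = np.array(
        [
            end_of_step_tension(m, P, StepProtocol(delta_l=float(d), delta_t=delta_t))
            / t_iso
            for d in dl
        ]
    )
    step_norm = step_norm + sigma * rng.standard_normal(n_steps)
    mu0_obs = meas.mu0_iso * (1.0 + sigma * rng.standard_normal())

    return SyntheticDataset(
        fv_v=v,
        fv_tension_pa=fv_tension,
        step_dl=dl,
        step_tension_norm=step_norm,
        step_dt=np.full(n_steps, delta_t),
        mu0_iso_obs=float(mu0_obs),
        growth=m.q.growth,
        sigma=sigma,
        seed=seed,
    )


def _normalized_fv_model(v, c1, c2):
    den = 1.0 + c1 * v
    return 1.0 / den - c2 * v / den**2


def _normalized_step_model(dl, dt, r0, c1, c2, growth):
    """Normalized end-of-step tension for candidate (r0, alpha=c1*r0,
    ratio=c2*r0); vectorized over dl."""
    alpha = c1 * r0
    ratio = c2 * r0
    out = np.empty_like(dl)
    for i, (d, t) in enumerate(zip(dl, dt)):
        if d == 0.0:
            out[i] = 1.0
            continue
        v = d / t
        q = QSpec(alpha=alpha, growth=growth)
        r = r0 + q(v)
        e = math.exp(-r * t)
        mu1_over = (
            1.0 / r0
            + ((1.0 / r - 1.0 / r0) - ratio * d / (r**2 * t)) * (1.0 - e)
            + ratio * (1.0 / r - 1.0 / r0) * d * e
        )
        out[i] = mu1_over * r0
    return out


def recover_measurements(d: SyntheticDataset) -> MeasuredQuantities:
    """Estimate the five macroscopic quantities from a synthetic dataset.

    The force-velocity points are fitted by nonlinear least squares to the
    closed-form curve ``T(v) = T_iso [1/(1+c1 v) - c2 v/(1+c1 v)^2]``
    (parameters T_iso, c1 = alpha/r0, c2 = (mu_f0/mu_f1)/r0), giving
    ``v0 = 1/(c1 + c2)`` and the zero crossing ``v_max = 1/(c2 - c1)``.
    The step points then identify the remaining time scale r0 through a
    one-dimensional fit of the end-of-step closed form (the step duration
    and growth class are part of the protocol), from which
    ``k2_tilde = c2 r0`` (sublinear) or ``(c1 + c2) r0`` (linear).  With
    sigma = 0 the recovery is exact to optimizer tolerance.
    """
    v, T = np.asarray(d.fv_v, float), np.asarray(d.fv_tension_pa, float)
    if v.min() > 0.0:
        raise ValueError("dataset must include v = 0")
    if np.all(T > 0.0):
        raise ValueError("zero crossing not bracketed by the dataset")

    # Initial guesses from the raw points.
    t_iso0 = float(T[np.argmin(v)])
    i_neg = int(np.argmax(T <= 0.0))
    v_cross0 = float(
        np.interp(0.0, [T[i_neg], T[i_neg - 1]], [v[i_neg], v[i_neg - 1]])
    )
    pos = v > 0
    slope0 = float(np.min((T[pos] / t_iso0 - 1.0) / v[pos]))
    v0_0 = max(-1.0 / min(slope0, -1e-12), 0.05 * v_cross0)
    c1_0 = max(0.5 * (1.0 / v0_0 - 1.0 / v_cross0), 1e-9)
    c2_0 = 1.0 / v0_0 - c1_0

    def fv_resid(theta):
        t_iso, c1, c2 = theta
        return t_iso * _normalized_fv_model(v, c1, c2) - T

    sol = optimize.least_squares(
        fv_resid,
        x0=[t_iso0, c1_0, c2_0],
        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    t_iso, c1, c2 = sol.x
    if c2 <= c1:
        raise ValueError("fitted curve has no positive zero crossing")
    v_max = 1.0 / (c2 - c1)
    v0 = 1.0 / (c1 + c2)

    # One-dimensional fit of r0 on the normalized step curve.
    dl = np.asarray(d.step_dl, float)
    sn = np.asarray(d.step_tension_norm, float)
    dt = np.asarray(d.step_dt, float)
    growth = GrowthKind(d.growth)

    small = dl <= max(0.011, dl[1] if dl.size > 1 else 0.011)
    k2_0 = max(
        float(-np.polyfit(dl[small], sn[small], 1)[0]), (c1 + c2) * 1e-3
    )
    r0_0 = k2_0 / (c2 if growth is GrowthKind.SUBLINEAR else (c1 + c2))

    def step_resid(log_r0):
        r0 = math.exp(log_r0[0])
        return _normalized_step_model(dl, dt, r0, c1, c2, growth) - sn

    sol2 = optimize.least_squares(
        step_resid, x0=[math.log(max(r0_0, 1e-3))],
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    r0 = math.exp(sol2.x[0])
    if growth is GrowthKind.SUBLINEAR:
        k2 = c2 * r0
    else:
        k2 = (c1 + c2) * r0

    return MeasuredQuantities(
        t_iso=float(t_iso),
        mu0_iso=float(d.mu0_iso_obs),
        v_max=float(v_max),
        v0=float(v0),
        k2_tilde=float(k2),
    )
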