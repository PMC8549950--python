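"""Exact two-moment ODE reduction of the generalized crossbridge model.

When the total transition rate ``f + g = r(v)`` is independent of the
displacement ``x``, the transport PDE reduces exactly to two ODEs for the
dimensionless distribution moments

    mu^p(t) = int (x/(SL0/2))^p n(x,t) dx / D_M ,   p = 0, 1:

    d(mu0)/dt = -r(v) mu0 + P mu_f0
    d(mu1)/dt = -r(v) mu1 + P mu_f1 - mu0 v

with ``r(v) = r0 + q(v)`` and active tension ``T_a = a_XB mu1``.  ``mu0`` is
the fraction of binding sites engaged in a crossbridge and ``mu1/mu0`` the
mean (normalized) crossbridge distortion.

The module provides the numerical solver, the closed-form steady state and
constant-velocity solution, the end-of-step tension after a rectangular
velocity pulse, the asymptotic instantaneous-step laws for the three growth
classes of ``q``, and the five macroscopic characteristic quantities
(T_a_iso, mu0_iso, v_max, v0, k2_tilde) used for calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .ratelib import GrowthKind, MomentRateParams, QSpec, q_of_v

__all__ = [
    "MomentState",
    "MomentTrajectory",
    "MeasuredQuantities",
    "StepProtocol",
    "solve_moments",
    "steady_moments",
    "analytic_constant_v",
    "end_of_step_tension",
    "asymptotic_step_tension",
    "normalized_force_velocity",
    "characteristic_quantities",
]


@dataclass(frozen=True)
class MomentState:
    """Moment pair (mu0, mu1) at a time point (all dimensionless, t in s)."""

    mu0: float
    mu1: float
    t: float = 0.0


@dataclass
class MomentTrajectory:
    """Time series of the two moments; tension is ``a_xb * mu1``."""

    t: np.ndarray
    mu0: np.ndarray
    mu1: np.ndarray
    a_xb: float = 1.0

    @property
    def tension(self) -> np.ndarray:
        return self.a_xb * self.mu1

    def at(self, i: int) -> MomentState:
        return MomentState(mu0=float(self.mu0[i]), mu1=float(self.mu1[i]), t=float(self.t[i]))


@dataclass(frozen=True)
class MeasuredQuantities:
    """The five macroscopic observables that identify the model.

    t_iso: isometric active tension (Pa); mu0_iso: isometric attached
    fraction (dimensionless); v_max: zero-tension velocity (1/s); v0:
    inverse normalized force-velocity slope at v=0 (1/s); k2_tilde:
    normalized small-step stiffness of the fast (T2) response.
    """

    t_iso: float
    mu0_iso: float
    v_max: float
    v0: float
    k2_tilde: float

    def __post_init__(self) -> None:
        for name in ("t_iso", "mu0_iso", "v0", "k2_tilde"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if math.isfinite(self.v_max) and self.v_max <= self.v0:
            raise ValueError("v_max must exceed v0")


@dataclass(frozen=True)
class StepProtocol:
    """Sudden shortening by ``delta_l`` (relative to half-sarcomere length)
    applied as a rectangular velocity pulse of duration ``delta_t`` (s)."""

    delta_l: float
    delta_t: float

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")

    @property
    def v_bar(self) -> float:
        return self.delta_l / self.delta_t


def isometric_state(m: MomentRateParams, P: float) -> MomentState:
    """Isometric steady state mu0 = P mu_f0/r0, mu1 = P mu_f1/r0."""
    return MomentState(mu0=P * m.mu_f0 / m.r0, mu1=P * m.mu_f1 / m.r0, t=0.0)


def solve_moments(
    m: MomentRateParams,
    P: float,
    v_of_t: Union[float, Callable[[float], float]],
    init: MomentState,
    t_end: float,
    t_eval: Optional[np.ndarray] = None,
    breaks: Sequence[float] = (),
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> MomentTrajectory:
    """Integrate the moment ODEs with an adaptive stiff-capable solver.

    ``v_of_t`` is the normalized velocity schedule (1/s), a constant or a
    callable; ``breaks`` lists discontinuity times of the schedule, and the
    integration is restarted at each so that step protocols are resolved
    exactly.  Tolerances default to 1e-10 because ``r(v)`` spans 1e1-1e3 1/s
    during fast steps.
    """
    v_fn = (lambda t: float(v_of_t)) if np.isscalar(v_of_t) else v_of_t

    def rhs(t, y):
        v = v_fn(t)
        r = m.r(v)
        return [
            -r * y[0] + P * m.mu_f0,
            -r * y[1] + P * m.mu_f1 - y[0] * v,
        ]

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    t_eval = np.asarray(t_eval, dtype=float)

    edges = [0.0] + sorted(b for b in breaks if 0.0 < b < t_end) + [t_end]
    ts, y0s, y1s = [], [], []
    y = [init.mu0, init.mu1]
    for a, b in zip(edges[:-1], edges[1:]):
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        seg_eval = np.union1d(seg_eval, [a, b])
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", t_eval=seg_eval, rtol=rtol, atol=atol
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"moment ODE solver failed: {sol.message}")
        keep = np.isin(sol.t, t_eval)
        ts.append(sol.t[keep])
        y0s.append(sol.y[0][keep])
        y1s.append(sol.y[1][keep])
        y = [sol.y[0][-1], sol.y[1][-1]]

    t = np.concatenate(ts)
    mu0 = np.concatenate(y0s)
    mu1 = np.concatenate(y1s)
    t, idx = np.unique(t, return_index=True)
    return MomentTrajectory(t=t, mu0=mu0[idx], mu1=mu1[idx], a_xb=m.a_xb)


def steady_moments(m: MomentRateParams, P: float, v: float):
    """Closed-form steady state at constant normalized velocity ``v``.

    ``mu0 = P mu_f0/r(v)``, ``mu1 = P (mu_f1/r(v) - mu_f0 v / r(v)^2)``;
    the steady tension is ``a_xb * mu1``.
    """
    r = m.r(v)
    mu0 = P * m.mu_f0 / r
    mu1 = P * (m.mu_f1 / r - m.mu_f0 * v / r**2)
    return mu0, mu1


def analytic_constant_v(
    m: MomentRateParams, P: float, v_bar: float, init: MomentState, t: float
) -> MomentState:
    """Exact solution of the moment ODEs for constant velocity ``v_bar``.

    Includes the secular ``t exp(-r t)`` term of ``mu1`` generated by the
    relaxation of ``mu0``.
    """
    r = m.r(v_bar)
    mu0_inf, mu1_inf = steady_moments(m, P, v_bar)
    e = math.exp(-r * t)
    mu0 = init.mu0 + (mu0_inf - init.mu0) * (1.0 - e)
    mu1 = (
        init.mu1
        + (mu1_inf - init.mu1) * (1.0 - e)
        + (mu0_inf - init.mu0) * v_bar * t * e
    )
    return MomentState(mu0=mu0, mu1=mu1, t=init.t + t)


def end_of_step_tension(m: MomentRateParams, P: float, step: StepProtocol) -> float:
    """Tension (Pa) at the end of a rectangular velocity pulse.

    Starts from the isometric steady state and applies
    ``v(t) = (delta_l/delta_t) 1_[0, delta_t](t)``; the result is the exact
    constant-velocity solution evaluated at ``t = delta_t``.
    """
    if step.delta_l == 0.0:
        return m.a_xb * P * m.mu_f1 / m.r0
    v_bar = step.v_bar
    r = m.r(v_bar)
    d = step.delta_t
    e = math.exp(-r * d)
    mu1 = P * (
        m.mu_f1 / m.r0
        + (m.mu_f1 * (1.0 / r - 1.0 / m.r0) - m.mu_f0 * step.delta_l / (r**2 * d))
        * (1.0 - e)
        + m.mu_f0 * (1.0 / r - 1.0 / m.r0) * step.delta_l * e
    )
    return m.a_xb * mu1


def asymptotic_step_tension(
    m: MomentRateParams,
    P: float,
    delta_l: float,
    growth: Optional[GrowthKind] = None,
) -> float:
    """Instantaneous-step (delta_t -> 0) tension limit, by growth class.

    Sublinear (and saturating) growth gives the linear-elastic law
    ``a_xb P (mu_f1 - mu_f0 dL)/r0``; linear growth damps it by
    ``exp(-alpha dL)``; superlinear growth destroys all crossbridges
    (tension 0 for any dL > 0).
    """
    growth = GrowthKind(growth) if growth is not None else m.q.growth
    base = m.a_xb * P * (m.mu_f1 - m.mu_f0 * delta_l) / m.r0
    if growth is GrowthKind.SUBLINEAR:
        return base
    if growth is GrowthKind.LINEAR:
        return base * math.exp(-m.q.alpha * delta_l)
    if growth is GrowthKind.SUPERLINEAR:
        return 0.0 if delta_l != 0.0 else m.a_xb * P * m.mu_f1 / m.r0
    raise ValueError(f"unknown growth kind {growth!r}")  # pragma: no cover


def normalized_force_velocity(m: MomentRateParams, v):
    """Steady tension over isometric tension at normalized velocity ``v``.

    Evaluates the closed form

        T/T_iso = 1/(1 + alpha|v|/r0) - (mu_f0/mu_f1) (v/r0) / (1 + alpha|v|/r0)^2

    i.e. the force-velocity-range convention ``q(v) = alpha |v|`` (for the
    sublinear class this is its small-velocity form; only the large-|v|
    tail differs between growth classes).  Independent of P and a_xb.
    """
    v = np.asarray(v, dtype=float)
    den = 1.0 + m.q.alpha * np.abs(v) / m.r0
    out = 1.0 / den - m.ratio * (v / m.r0) / den**2
    return out if out.ndim else float(out)


def characteristic_quantities(m: MomentRateParams, P: float) -> MeasuredQuantities:
    """Forward map from model parameters to the five macroscopic observables.

    ``T_iso = a_xb P mu_f1/r0``; ``mu0_iso = P mu_f0/r0``;
    ``v_max = r0/(mu_f0/mu_f1 - alpha)`` (infinite, with a warning, when
    ``alpha >= mu_f0/mu_f1``: the force-velocity curve never crosses zero);
    ``v0 = r0/(mu_f0/mu_f1 + alpha)``; ``k2_tilde = mu_f0/mu_f1`` for
    sublinear growth, ``mu_f0/mu_f1 + alpha`` otherwise (the paper-standard
    linear-growth relationship, also used for the superlinear experiments).
    """
    ratio = m.ratio
    alpha = m.q.alpha
    if alpha >= ratio:
        warnings.warn(
            "alpha >= mu_f0/mu_f1: v_max is undefined (force-velocity curve "
            "never intercepts zero)",
            RuntimeWarning,
            stacklevel=2,
        )
        v_max = math.inf
    else:
        v_max = m.r0 / (ratio - alpha)
    v0 = m.r0 / (ratio + alpha)
    if m.q.growth is GrowthKind.SUBLINEAR:
        k2 = ratio
    else:
        k2 = ratio + alpha
    return MeasuredQuantities(
        t_iso=m.a_xb * P * m.mu_f1 / m.r0,
        mu0_iso=P * m.mu_f0 / m.r0,
        v_max=v_max,
        v0=v0,
        k2_tilde=k2,
    )
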