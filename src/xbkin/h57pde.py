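"""Gridded solver for the two-state sliding-filament transport PDE.

The model evolves the attached-fraction density ``n(x, t)`` of
myosin-head/binding-site pairs with displacement ``x`` (nm):

    dn/dt - v_hs(t) dn/dx = (P - n) f(x, v) - n g(x, v)

where ``v_hs`` (nm/s) is the half-sarcomere shortening velocity and ``P``
the permissivity (fraction of binding sites made available by calcium).
The force per half-filament is ``F_hf = rho_AM k_XB int x n dx``.

The solver splits advection (first-order upwind, zero-inflow boundaries)
from the reaction, which is linear in ``n`` and therefore integrated
exactly per step (``n -> n_eq + (n - n_eq) exp(-(f+g) dt)``), removing the
stiffness of the fast detachment branch.

The classic Huxley steady state and its closed-form force-velocity curve
are provided as analytic oracles.  Note that the steady profile for
``x < 0`` decays as ``exp(g2 x / v_hs)`` -- the rate required for the
profile to satisfy the PDE and to integrate to the closed-form
force-velocity expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
from scipy import optimize

from .ratelib import HuxleyRateParams, huxley_f, huxley_g

__all__ = [
    "Grid",
    "DistributionState",
    "FilamentForceParams",
    "solve_h57",
    "analytic_huxley_steady",
    "huxley_force_velocity",
    "huxley_vmax",
    "force_from_distribution",
]


@dataclass(frozen=True)
class Grid:
    """Uniform displacement grid (nm) for the transport equation."""

    x_min: float = -40.0
    x_max: float = 25.0
    n_points: int = 1300

    def __post_init__(self) -> None:
        if not (self.x_min < 0.0 < self.x_max):
            raise ValueError("grid must straddle x = 0")
        if self.n_points < 3:
            raise ValueError("need at least 3 grid points")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.x_max - self.x_min) / (self.n_points - 1)


@dataclass
class DistributionState:
    """Attached-fraction density sampled on a grid at one time point."""

    grid: Grid
    n: np.ndarray
    t: float = 0.0
    P: float = 1.0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.shape != (self.grid.n_points,):
            raise ValueError("density shape does not match grid")
        if np.any(self.n < -1e-12) or np.any(self.n > self.P + 1e-12):
            raise ValueError("initial density out of [0, P]")


@dataclass(frozen=True)
class FilamentForceParams:
    """Force scale of one half thick filament / thin filament pair.

    ``rho_am`` is the line density of actin-myosin pairs (1/nm) and
    ``k_xb`` the crossbridge stiffness (pN/nm, experimentally ~2).
    """

    rho_am: float = 1.0
    k_xb: float = 2.0

    def __post_init__(self) -> None:
        if self.rho_am <= 0 or self.k_xb <= 0:
            raise ValueError("rho_am and k_xb must be positive")


def _as_rate_fn(rate, v: float) -> Callable[[np.ndarray], np.ndarray]:
    """Accept either f(x) or f(x, v) callables."""
    try:
        rate(np.zeros(1), v)
    except TypeError:
        return lambda x: np.asarray(rate(x), dtype=float)
    return lambda x: np.asarray(rate(x, v), dtype=float)


def solve_h57(
    f,
    g,
    P: float,
    v_of_t: Union[float, Callable[[float], float]],
    n_init: DistributionState,
    t_end: float,
    grid: Optional[Grid] = None,
    sl0: float = 2200.0,
    cfl: float = 0.9,
    n_save: int = 11,
) -> List[DistributionState]:
    """Integrate the transport PDE and return saved states.

    Parameters
    ----------
    f, g
        Attachment / detachment rates, callables of ``x`` (nm) or of
        ``(x, v)`` with ``v`` the normalized velocity ``v_hs/(SL0/2)``.
    P
        Permissivity in (0, 1].
    v_of_t
        Half-sarcomere shortening velocity schedule (nm/s): a constant or a
        callable of time.  Positive values shorten (convect ``n`` towards
        negative ``x``).
    n_init
        Initial state; its grid is used unless ``grid`` overrides it.
    t_end
        Final time (s).
    n_save
        Number of equally spaced output states, including t=0 and t_end.
    """
    if grid is None:
        grid = n_init.grid
    if not 0.0 < P <= 1.0:
        raise ValueError("P must lie in (0, 1]")
    x = grid.x
    dx = grid.spacing
    v_fn = (lambda t: float(v_of_t)) if np.isscalar(v_of_t) else v_of_t

    # Bound the velocity over the horizon to pick a CFL-stable step.
    t_probe = np.linspace(0.0, t_end, 257)
    v_abs_max = max(abs(v_fn(float(t))) for t in t_probe)
    if v_abs_max > 0:
        dt = cfl * dx / v_abs_max
    else:
        dt = t_end / 200.0 if t_end > 0 else 1.0
    n_steps = max(1, int(math.ceil(t_end / dt)))
    dt = t_end / n_steps

    n = n_init.n.copy()
    save_times = np.linspace(0.0, t_end, n_save)
    out: List[DistributionState] = [
        DistributionState(grid=grid, n=n.copy(), t=0.0, P=P)
    ]
    next_save = 1

    t = 0.0
    rate_cache = {}
    for _ in range(n_steps):
        v_hs = v_fn(t)
        if abs(v_hs) * dt > dx * (1.0 + 1e-9):
            raise RuntimeError("CFL condition violated by velocity schedule")
        vnorm = v_hs / (sl0 / 2.0)
        key = round(vnorm, 15)
        if key not in rate_cache:
            fx = np.clip(_as_rate_fn(f, vnorm)(x), 0.0, None)
            gx = np.clip(_as_rate_fn(g, vnorm)(x), 0.0, None)
            tot = fx + gx
            with np.errstate(invalid="ignore", divide="ignore"):
                neq = np.where(tot > 0.0, P * fx / np.where(tot > 0, tot, 1.0), 0.0)
            rate_cache[key] = (tot, neq)
        tot, neq = rate_cache[key]

        # Advection: dn/dt = v_hs dn/dx, upwind with zero inflow.
        if v_hs > 0:
            n_shift = np.empty_like(n)
            n_shift[:-1] = n[1:]
            n_shift[-1] = 0.0
            n = n + (v_hs * dt / dx) * (n_shift - n)
        elif v_hs < 0:
            n_shift = np.empty_like(n)
            n_shift[1:] = n[:-1]
            n_shift[0] = 0.0
            n = n + (-v_hs * dt / dx) * (n_shift - n)

        # Reaction: exact exponential relaxation towards P f/(f+g).
        decay = np.exp(-tot * dt)
        n = np.where(tot > 0.0, neq + (n - neq) * decay, n)

        t += dt
        while next_save < n_save and t >= save_times[next_save] - 1e-12:
            out.append(DistributionState(grid=grid, n=n.copy(), t=float(t), P=P))
            next_save += 1

    if len(out) < n_save:
        out.append(DistributionState(grid=grid, n=n.copy(), t=t_end, P=P))
    return out


def analytic_huxley_steady(x, v_hs: float, p: HuxleyRateParams):
    """Steady attached fraction of the classic model at shortening ``v_hs > 0``.

    For ``0 <= x < h``: ``F1 (1 - exp((x^2/h^2 - 1) phi/v_hs))``; for
    ``x < 0`` the profile decays as ``exp(g2 x / v_hs)`` from its value at
    ``x = 0``; zero for ``x >= h``.
    """
    if v_hs <= 0:
        raise ValueError("v_hs must be > 0; use the v->0 limit for isometric")
    x = np.asarray(x, dtype=float)
    F1, phi = p.F1, p.phi
    n0 = F1 * (1.0 - math.exp(-phi / v_hs))
    mid = F1 * (1.0 - np.exp(np.clip((x**2 / p.h**2 - 1.0) * phi / v_hs, None, 0.0)))
    left = n0 * np.exp(np.minimum(p.g2 * x / v_hs, 0.0))
    out = np.where(x < 0.0, left, np.where(x < p.h, mid, 0.0))
    return out if out.ndim else float(out)


def huxley_isometric_steady(x, p: HuxleyRateParams):
    """Pointwise v_hs -> 0+ limit of the steady profile: F1 on (0, h), else 0."""
    x = np.asarray(x, dtype=float)
    out = np.where((x > 0.0) & (x < p.h), p.F1, 0.0)
    return out if out.ndim else float(out)


def huxley_force_velocity(
    v_hs: float, p: HuxleyRateParams, fp: FilamentForceParams = FilamentForceParams()
) -> float:
    """Closed-form steady force (pN per half filament) at shortening ``v_hs >= 0``.

    ``F_hf = rho_AM k_XB F1 h^2/2 [1 - (v/phi)(1 - e^{-phi/v})(1 + (v/phi)/(2 G2^2))]``
    with the isometric value ``rho_AM k_XB F1 h^2/2`` at ``v_hs = 0``.
    """
    scale = fp.rho_am * fp.k_xb * p.F1 * p.h**2 / 2.0
    if v_hs < 0:
        raise ValueError("v_hs must be >= 0")
    if v_hs == 0:
        return scale
    s = v_hs / p.phi
    bracket = 1.0 - s * (1.0 - math.exp(-1.0 / s)) * (1.0 + s / (2.0 * p.G2**2))
    return scale * bracket


def huxley_vmax(p: HuxleyRateParams, s_hi: float = 50.0) -> float:
    """Maximum shortening velocity (nm/s): positive root of the force display.

    Solved by bracketed root finding in the reduced variable ``s = v_hs/phi``
    (for Huxley's fitted constants the root sits near ``s = 4``).
    """

    def bracket(s: float) -> float:
        return 1.0 - s * (1.0 - math.exp(-1.0 / s)) * (1.0 + s / (2.0 * p.G2**2))

    lo = 1e-9
    if bracket(s_hi) >= 0:
        raise ValueError("no zero crossing in bracket; increase s_hi")
    s_root = optimize.brentq(bracket, lo, s_hi, xtol=1e-14, rtol=1e-14)
    return s_root * p.phi


def force_from_distribution(
    s: DistributionState, fp: FilamentForceParams = FilamentForceParams()
) -> float:
    """Force (pN) from a gridded density: rho_AM k_XB * trapezoid of x n(x)."""
    x = s.grid.x
    return fp.rho_am * fp.k_xb * float(np.trapezoid(x * s.n, x))


def grid_moments(
    s: DistributionState, sl0: float = 2200.0, d_m: float = 43.0
) -> tuple:
    """Dimensionless moments (mu0, mu1) of a gridded density.

    ``mu_p = int (x/(SL0/2))^p n(x) dx / D_M`` by the trapezoidal rule;
    used to cross-check the PDE solution against the moment ODEs.
    """
    x = s.grid.x
    mu0 = float(np.trapezoid(s.n, x)) / d_m
    mu1 = float(np.trapezoid((x / (sl0 / 2.0)) * s.n, x)) / d_m
    return mu0, mu1
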