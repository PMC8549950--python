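"""Thermal-equilibrium reduction of a soft-spin power-stroke motor to
effective two-state attachment/detachment rates.

A myosin head is described by two continuous degrees of freedom: the tip
position ``z`` and the power-stroke coordinate ``y`` (nm), with energy
``w_omega(z, y) = u_omega(y) + u_e(z + y)`` where ``u_e`` is the quadratic
myosin-arm energy and ``u_omega`` the (typically bistable) internal energy
of the detached (omega = 0) or attached (omega = 1) state.  When the head
is attached, ``z`` coincides with the displacement ``x``.

If the macroscopic time scales are slow enough for (z, y) to be at thermal
equilibrium, the microscopic attachment/detachment rates ``k_plus(z, y, x)``
and ``k_minus(y, x)`` average against the Boltzmann densities

    p0(z, y)   ~ exp(-w_0(z, y)/kBT)      (detached, normalized over z, y)
    p1(y; x)   ~ exp(-w_1(x, y)/kBT)      (attached, normalized over y)

to give displacement-dependent effective rates

    f_th(x) = integral k_plus(z, y, x) p0(z, y) dz dy
    g_th(x) = integral k_minus(y, x) p1(y; x) dy

i.e. a closed two-state model of the classic sliding-filament form.  This
module is an engine over user-supplied energies and rates; energies are in
zeptojoules (1 zJ = 1 pN nm), consistent with stiffnesses in pN/nm and
kBT ~ 4.1 zJ at room temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = [
    "EnergyLandscape",
    "ThermalParams",
    "equilibrium_density_detached",
    "equilibrium_density_attached",
    "effective_rates",
    "toy_landscape",
    "suggest_grid",
    "auto_grids",
]


@dataclass(frozen=True)
class EnergyLandscape:
    """Composed energy w_omega(z, y) = u_omega(y) + u_e(z + y), in zJ.

    ``u_detached``/``u_attached`` are callables of the power-stroke
    coordinate y (nm); the elastic arm energy is quadratic with stiffness
    ``k_xb`` (pN/nm).  Both composed energies must grow unboundedly so the
    Boltzmann factors are integrable.
    """

    u_detached: Callable[[np.ndarray], np.ndarray]
    u_attached: Callable[[np.ndarray], np.ndarray]
    k_xb: float = 2.0

    def u_elastic(self, s):
        return 0.5 * self.k_xb * np.asarray(s, dtype=float) ** 2

    def w_detached(self, z, y):
        return self.u_detached(np.asarray(y, float)) + self.u_elastic(
            np.asarray(z, float) + np.asarray(y, float)
        )

    def w_attached(self, x, y):
        return self.u_attached(np.asarray(y, float)) + self.u_elastic(x + np.asarray(y, float))


@dataclass(frozen=True)
class ThermalParams:
    """Thermal energy scale kBT in zJ (~4.1 at room temperature)."""

    kbt: float = 4.1

    def __post_init__(self) -> None:
        if self.kbt <= 0:
            raise ValueError("kBT must be positive")


def suggest_grid(
    energy_1d: Callable[[np.ndarray], np.ndarray],
    th: ThermalParams,
    lo: float = -100.0,
    hi: float = 100.0,
    n: int = 801,
    cutoff_kbt: float = 40.0,
) -> np.ndarray:
    """Uniform grid covering the region where the energy is within
    ``cutoff_kbt * kBT`` of its minimum (Boltzmann tail mass negligible)."""
    scan = np.linspace(lo, hi, 4001)
    w = np.asarray(energy_1d(scan), dtype=float)
    keep = w - w.min() <= cutoff_kbt * th.kbt
    if not keep.any():  # pragma: no cover
        raise ValueError("energy has no finite minimum on the scan range")
    return np.linspace(scan[keep].min(), scan[keep].max(), n)


def _boltzmann_2d(E: EnergyLandscape, th: ThermalParams, z_grid, y_grid):
    Z, Y = np.meshgrid(z_grid, y_grid, indexing="ij")
    w = E.w_detached(Z, Y)
    w = w - w.min()
    if w[0, :].min() < 25 * th.kbt or w[-1, :].min() < 25 * th.kbt:
        raise ValueError("z grid truncates the Boltzmann factor too tightly")
    if w[:, 0].min() < 25 * th.kbt or w[:, -1].min() < 25 * th.kbt:
        raise ValueError("y grid truncates the Boltzmann factor too tightly")
    return np.exp(-w / th.kbt)


def equilibrium_density_detached(
    E: EnergyLandscape, th: ThermalParams, z_grid: np.ndarray, y_grid: np.ndarray
) -> np.ndarray:
    """Normalized Boltzmann density of the detached state on (z, y).

    Returns an array of shape (len(z_grid), len(y_grid)) integrating to 1
    under the trapezoidal rule; invariant to constant energy shifts.
    """
    b = _boltzmann_2d(E, th, z_grid, y_grid)
    norm = np.trapezoid(np.trapezoid(b, y_grid, axis=1), z_grid)
    return b / norm


def equilibrium_density_attached(
    E: EnergyLandscape, th: ThermalParams, x: float, y_grid: np.ndarray
) -> np.ndarray:
    """Normalized Boltzmann density of the attached state over y at fixed x."""
    w = E.w_attached(x, y_grid)
    w = w - w.min()
    if min(w[0], w[-1]) < 25 * th.kbt:
        raise ValueError("y grid truncates the Boltzmann factor too tightly")
    b = np.exp(-w / th.kbt)
    return b / np.trapezoid(b, y_grid)


def effective_rates(
    k_plus: Callable[..., np.ndarray],
    k_minus: Callable[..., np.ndarray],
    E: EnergyLandscape,
    th: ThermalParams,
    x: float,
    z_grid: np.ndarray,
    y_grid: np.ndarray,
) -> Tuple[float, float]:
    """Effective attachment/detachment rates at displacement x (1/s).

    ``k_plus(z, y, x)`` is averaged against the detached equilibrium
    density, ``k_minus(y, x)`` against the attached one; constant rates pass
    through unchanged and pinning y = 0 reduces g to ``k_minus(0, x)``.
    """
    p0 = equilibrium_density_detached(E, th, z_grid, y_grid)
    Z, Y = np.meshgrid(z_grid, y_grid, indexing="ij")
    kp = np.broadcast_to(np.asarray(k_plus(Z, Y, x), dtype=float), p0.shape)
    f_th = float(np.trapezoid(np.trapezoid(kp * p0, y_grid, axis=1), z_grid))

    p1 = equilibrium_density_attached(E, th, x, y_grid)
    km = np.broadcast_to(np.asarray(k_minus(y_grid, x), dtype=float), p1.shape)
    g_th = float(np.trapezoid(km * p1, y_grid))
    return f_th, g_th


def auto_grids(
    E: EnergyLandscape,
    th: ThermalParams,
    span: float = 120.0,
    n: int = 401,
    cutoff_kbt: float = 40.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Detached-state (z, y) grids from a coarse 2D energy scan.

    Scans ``[-span, span]^2``, keeps the box where ``w0 - min(w0)`` is within
    ``cutoff_kbt * kBT`` and pads it so the boundary check of the density
    routines is satisfied.
    """
    coarse = np.linspace(-span, span, 241)
    Z, Y = np.meshgrid(coarse, coarse, indexing="ij")
    w = E.w_detached(Z, Y)
    w = w - w.min()
    keep = w <= cutoff_kbt * th.kbt
    z_keep = coarse[keep.any(axis=1)]
    y_keep = coarse[keep.any(axis=0)]
    pad = 0.35
    z_lo, z_hi = z_keep.min(), z_keep.max()
    y_lo, y_hi = y_keep.min(), y_keep.max()
    z_grid = np.linspace(z_lo - pad * (z_hi - z_lo), z_hi + pad * (z_hi - z_lo), n)
    y_grid = np.linspace(y_lo - pad * (y_hi - y_lo), y_hi + pad * (y_hi - y_lo), n)
    return z_grid, y_grid


def toy_landscape(
    k_xb: float = 2.0,
    stroke: float = 8.0,
    barrier: float = 12.0,
    bias: float = 8.0,
    k_detached: float = 1.0,
) -> EnergyLandscape:
    """Packaged double-well test landscape (used by the test suite).

    Detached state: single quadratic well at y = 0 with stiffness
    ``k_detached`` (pN/nm).  Attached state: quartic double well with minima
    near y = 0 (pre power stroke) and y = ``stroke`` (post power stroke),
    barrier height ``barrier`` (zJ) and a ``bias`` (zJ) tilt that lowers the
    post-stroke well.
    """

    def u_det(y):
        return 0.5 * k_detached * np.asarray(y, float) ** 2

    a = float(stroke)

    def u_att(y):
        y = np.asarray(y, float)
        return 16.0 * barrier * (y / a) ** 2 * (y / a - 1.0) ** 2 - bias * y / a

    return EnergyLandscape(u_detached=u_det, u_attached=u_att, k_xb=k_xb)
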