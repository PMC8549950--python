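"""Crossbridge transition-rate models and parameter conversions.

This module defines the attachment/detachment rate families used throughout
the package:

* the classic Huxley 1957 rates ``f(x) = f1 x/h`` on ``[0, h]`` and
  ``g(x) = g2`` for ``x <= 0``, ``g1 x/h`` for ``x > 0``;
* the constant-window rates ``f(x) = k_ATP`` on ``[s0, s0 + h]`` with an
  x-independent total rate ``f + g = k_ATP + q(v)``;
* the velocity-dependent crossbridge-destruction term ``q(v)`` with
  sublinear (``alpha * sqrt|v|``), linear (``alpha * |v|``) and superlinear
  (``alpha * (|v| + v^2)``) growth.

Units are nanometres for lengths, 1/s for rates, and the normalized
shortening velocity ``v = v_hs / (SL0/2)`` (units 1/s) for velocities.
The macroscopic tension scale ``a_XB`` is stored in Pa.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import integrate

__all__ = [
    "SL0_DEFAULT_NM",
    "DM_DEFAULT_NM",
    "GrowthKind",
    "QSpec",
    "HuxleyRateParams",
    "MicroWindowParams",
    "MomentRateParams",
    "huxley_f",
    "huxley_g",
    "q_of_v",
    "window_rates",
    "micro_to_moment",
    "moment_to_micro",
    "moments_of_f",
]

#: Reference sarcomere length (nm).  Within the physiological 1.7-2.3 um
#: range and consistent with v = v_hs/(SL0/2) ~ 1.45 1/s at v_hs ~ 1600 nm/s.
SL0_DEFAULT_NM = 2200.0

#: Spacing between consecutive myosin heads along the thick filament (nm).
DM_DEFAULT_NM = 43.0


class GrowthKind(str, enum.Enum):
    """Asymptotic growth class of the destruction rate ``q(v)``.

    The growth class controls the instantaneous response to a length step:
    sublinear growth gives a linear-elastic drop, linear growth an
    exponentially damped drop, and superlinear growth destroys every
    crossbridge in the limit of an instantaneous step.
    """

    SUBLINEAR = "sublinear"
    LINEAR = "linear"
    SUPERLINEAR = "superlinear"


@dataclass(frozen=True)
class QSpec:
    """Velocity-dependent detachment (destruction) term ``q(v)``.

    ``q`` is even in ``v``, nonnegative, and vanishes at ``v = 0`` for every
    growth kind; ``alpha`` is dimensionless.
    """

    alpha: float
    growth: GrowthKind = GrowthKind.LINEAR

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        object.__setattr__(self, "growth", GrowthKind(self.growth))

    def __call__(self, v):
        return q_of_v(v, self)


def q_of_v(v, q: QSpec):
    """Evaluate the destruction rate ``q(v)`` (1/s) for normalized velocity ``v``.

    Sublinear: ``alpha*sqrt|v|``; linear: ``alpha*|v|``; superlinear:
    ``alpha*(|v| + v^2)``.  Accepts scalars or arrays.
    """
    av = np.abs(v)
    if q.growth is GrowthKind.SUBLINEAR:
        out = q.alpha * np.sqrt(av)
    elif q.growth is GrowthKind.LINEAR:
        out = q.alpha * av
    elif q.growth is GrowthKind.SUPERLINEAR:
        out = q.alpha * (av + av**2)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown growth kind {q.growth!r}")
    return out if isinstance(out, np.ndarray) and np.ndim(v) else float(out)


@dataclass(frozen=True)
class HuxleyRateParams:
    """Rate constants of the classic Huxley 1957 model.

    ``f1``, ``g1``, ``g2`` are positive rates (1/s) and ``h`` (nm) is the
    width of the attachment window.  Derived constants: ``F1 = f1/(f1+g1)``
    (isometric attached fraction on the window), ``G2 = g2/(f1+g1)`` and the
    velocity scale ``phi = (f1+g1)*h/2`` (nm/s).
    """

    f1: float
    g1: float
    g2: float
    h: float

    def __post_init__(self) -> None:
        for name in ("f1", "g1", "g2", "h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def F1(self) -> float:
        return self.f1 / (self.f1 + self.g1)

    @property
    def G2(self) -> float:
        return self.g2 / (self.f1 + self.g1)

    @property
    def phi(self) -> float:
        """Characteristic velocity (f1+g1)*h/2 in nm/s."""
        return (self.f1 + self.g1) * self.h / 2.0


def huxley_f(x, p: HuxleyRateParams):
    """Huxley attachment rate: linear ramp ``f1*x/h`` on ``[0, h]``, else 0."""
    x = np.asarray(x, dtype=float)
    out = np.where((x >= 0.0) & (x <= p.h), p.f1 * x / p.h, 0.0)
    return out if out.ndim else float(out)


def huxley_g(x, p: HuxleyRateParams):
    """Huxley detachment rate: ``g2`` for ``x <= 0``, ``g1*x/h`` for ``x > 0``."""
    x = np.asarray(x, dtype=float)
    out = np.where(x <= 0.0, p.g2, p.g1 * x / p.h)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MicroWindowParams:
    """Microscopic description of the constant-window rate model.

    Attachment occurs at rate ``k_atp`` (the ATP turnover rate, 1/s) only for
    displacements ``x`` inside ``[s0, s0 + h]`` (nm); detachment is
    ``k_atp + q(v)`` outside the window and ``q(v)`` inside, so that the
    total rate ``f + g = k_atp + q(v)`` is independent of ``x``.
    """

    k_atp: float
    s0: float
    h: float
    q: QSpec
    d_m: float = DM_DEFAULT_NM
    sl0: float = SL0_DEFAULT_NM

    def __post_init__(self) -> None:
        if self.h <= 0 or self.d_m <= 0 or self.sl0 <= 0:
            raise ValueError("h, d_m and sl0 must be strictly positive")
        if self.k_atp <= 0:
            raise ValueError("k_atp must be strictly positive")


def window_rates(x, v, p: MicroWindowParams):
    """Attachment/detachment rates of the window model at ``(x, v)``.

    Returns ``(f, g)`` with ``f = k_atp`` inside ``[s0, s0+h]`` (closed
    endpoints) and 0 outside, and ``g = k_atp - f + q(v)``, so ``f + g``
    is exactly ``k_atp + q(v)`` for every ``x``.
    """
    x = np.asarray(x, dtype=float)
    inside = (x >= p.s0) & (x <= p.s0 + p.h)
    f = np.where(inside, p.k_atp, 0.0)
    g = p.k_atp - f + q_of_v(v, p.q)
    if f.ndim == 0:
        return float(f), float(g)
    return f, g


@dataclass(frozen=True)
class MomentRateParams:
    """Moment-level parameter vector of the generalized two-state model.

    ``mu_f0`` and ``mu_f1`` (1/s) are the zeroth and first dimensionless
    moments of the attachment rate, ``r0`` (1/s) the isometric total
    transition rate, ``q`` the destruction term and ``a_xb`` (Pa) the
    microscopic-to-macroscopic tension scale: ``T_a = a_xb * mu1``.
    """

    mu_f0: float
    mu_f1: float
    r0: float
    q: QSpec
    a_xb: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu_f0", "mu_f1", "r0", "a_xb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def r(self, v):
        """Total transition rate r(v) = r0 + q(v) (1/s)."""
        return self.r0 + q_of_v(v, self.q)

    @property
    def ratio(self) -> float:
        """The stiffness-like ratio mu_f0/mu_f1 (dimensionless)."""
        return self.mu_f0 / self.mu_f1


def micro_to_moment(p: MicroWindowParams, a_xb: float = 1.0) -> MomentRateParams:
    """Map the window-model description to moment-level parameters.

    ``mu_f0 = k_atp*h/D_M``, ``mu_f1 = k_atp*h*(h + 2 s0)/(SL0*D_M)``,
    ``r0 = k_atp``; the destruction term is passed through unchanged.  The
    tension scale ``a_xb`` is not part of the microscopic description and
    defaults to 1 Pa.
    """
    mu_f0 = p.k_atp * p.h / p.d_m
    mu_f1 = p.k_atp * p.h * (p.h + 2.0 * p.s0) / (p.sl0 * p.d_m)
    return MomentRateParams(mu_f0=mu_f0, mu_f1=mu_f1, r0=p.k_atp, q=p.q, a_xb=a_xb)


def moment_to_micro(
    m: MomentRateParams,
    d_m: float = DM_DEFAULT_NM,
    sl0: float = SL0_DEFAULT_NM,
) -> MicroWindowParams:
    """Invert :func:`micro_to_moment` (microscopical interpretation).

    ``k_atp = r0``, ``h = mu_f0 * D_M / k_atp`` and
    ``s0 = (SL0 * mu_f1/mu_f0 - h) / 2``; the composition with
    :func:`micro_to_moment` is the identity to machine precision.
    """
    k_atp = m.r0
    h = m.mu_f0 * d_m / k_atp
    if h <= 0:
        raise ValueError("inverse map produced non-positive window width h")
    s0 = 0.5 * (sl0 * m.mu_f1 / m.mu_f0 - h)
    return MicroWindowParams(k_atp=k_atp, s0=s0, h=h, q=m.q, d_m=d_m, sl0=sl0)


def moments_of_f(
    f: Callable[[np.ndarray], np.ndarray],
    p: int,
    sl0: float = SL0_DEFAULT_NM,
    d_m: float = DM_DEFAULT_NM,
    support: Tuple[float, float] = (-100.0, 100.0),
) -> float:
    """p-th dimensionless moment of an attachment-rate function (1/s).

    Computes ``mu_f^p = int (x/(SL0/2))^p f(x) dx / D_M`` by adaptive
    quadrature over ``support`` (nm), which must contain the support of
    ``f``.  Matches the closed forms of the window and Huxley families.
    """
    lo, hi = support
    if not lo < hi:
        raise ValueError("support must be an increasing interval")

    def integrand(x):
        return (x / (sl0 / 2.0)) ** p * f(x)

    val, err = integrate.quad(integrand, lo, hi, limit=400)
    if not math.isfinite(val):
        raise ValueError("moment integral did not converge")
    return val / d_m
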