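"""Closed-form calibration of the moment-level model from macroscopic data.

Five measured quantities -- the isometric tension T_iso, the isometric
attached fraction mu0_iso, the force-velocity intercepts v_max and v0, and
the normalized fast-step stiffness k2_tilde -- determine the five model
parameters (r0, alpha, mu_f0, mu_f1, a_xb) exactly, with one formula set
per growth class of the destruction term q(v):

linear growth (q = alpha|v|)::

    r0    = k2 * v0
    alpha = (k2/2) (1 - v0/v_max)
    mu_f0 = mu0_iso r0 / P
    mu_f1 = mu_f0 / (k2 - alpha)
    a_xb  = T_iso r0 / (mu_f1 P)

sublinear growth (q = alpha|v| near zero, sublinear tail)::

    r0    = 2 k2 v_max / (1 + v_max/v0)
    alpha = k2 (v_max - v0) / (v_max + v0)
    mu_f0 = mu0_iso r0 / P
    mu_f1 = mu_f0 / k2
    a_xb  = T_iso r0 / (mu_f1 P)

The forward map (moments.characteristic_quantities) composed with either
inverse is the identity; P is the permissivity under which T_iso and
mu0_iso were measured (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .moments import MeasuredQuantities, characteristic_quantities
from .ratelib import GrowthKind, MomentRateParams, QSpec

__all__ = [
    "CalibrationResult",
    "calibrate",
    "calibrate_linear",
    "calibrate_sublinear",
    "forward_measurements",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated parameter vector plus the permissivity used."""

    params: MomentRateParams
    growth: GrowthKind
    P_used: float


def _check(meas: MeasuredQuantities, P: float) -> None:
    if not 0.0 < P <= 1.0:
        raise ValueError("P must lie in (0, 1]")
    if meas.v0 >= meas.v_max:
        raise ValueError(
            "v0 >= v_max would give alpha <= 0: the measured force-velocity "
            "curve is not convex-decreasing as the model requires"
        )


def calibrate_linear(meas: MeasuredQuantities, P: float = 1.0) -> CalibrationResult:
    """Calibrate assuming linear growth of the destruction rate."""
    _check(meas, P)
    r0 = meas.k2_tilde * meas.v0
    alpha = 0.5 * meas.k2_tilde * (1.0 - meas.v0 / meas.v_max)
    mu_f0 = meas.mu0_iso * r0 / P
    mu_f1 = mu_f0 / (meas.k2_tilde - alpha)
    a_xb = meas.t_iso * r0 / (mu_f1 * P)
    params = MomentRateParams(
        mu_f0=mu_f0, mu_f1=mu_f1, r0=r0,
        q=QSpec(alpha=alpha, growth=GrowthKind.LINEAR), a_xb=a_xb,
    )
    return CalibrationResult(params=params, growth=GrowthKind.LINEAR, P_used=P)


def calibrate_sublinear(meas: MeasuredQuantities, P: float = 1.0) -> CalibrationResult:
    """Calibrate assuming sublinear growth of the destruction rate."""
    _check(meas, P)
    r0 = 2.0 * meas.k2_tilde * meas.v_max / (1.0 + meas.v_max / meas.v0)
    alpha = meas.k2_tilde * (meas.v_max - meas.v0) / (meas.v_max + meas.v0)
    mu_f0 = meas.mu0_iso * r0 / P
    mu_f1 = mu_f0 / meas.k2_tilde
    a_xb = meas.t_iso * r0 / (mu_f1 * P)
    params = MomentRateParams(
        mu_f0=mu_f0, mu_f1=mu_f1, r0=r0,
        q=QSpec(alpha=alpha, growth=GrowthKind.SUBLINEAR), a_xb=a_xb,
    )
    return CalibrationResult(params=params, growth=GrowthKind.SUBLINEAR, P_used=P)


def calibrate(
    meas: MeasuredQuantities, growth: GrowthKind, P: float = 1.0
) -> CalibrationResult:
    """Dispatch on growth kind.

    The superlinear kind reuses the linear-growth relationships (there is no
    closed-form inverse for it; the linear formulas with a user-chosen
    k2_tilde are the standard workaround) but tags the result superlinear so
    simulations use q = alpha(|v| + v^2).
    """
    growth = GrowthKind(growth)
    if growth is GrowthKind.SUBLINEAR:
        return calibrate_sublinear(meas, P)
    res = calibrate_linear(meas, P)
    if growth is GrowthKind.SUPERLINEAR:
        p = res.params
        params = MomentRateParams(
            mu_f0=p.mu_f0, mu_f1=p.mu_f1, r0=p.r0,
            q=QSpec(alpha=p.q.alpha, growth=GrowthKind.SUPERLINEAR), a_xb=p.a_xb,
        )
        return CalibrationResult(params=params, growth=growth, P_used=P)
    return res


def forward_measurements(res: CalibrationResult) -> MeasuredQuantities:
    """Forward map of a calibration result back to the measured quantities."""
    return characteristic_quantities(res.params, res.P_used)
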