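import numpy as np
import pytest

from xbkin import (
    HuxleyRateParams,
    MeasuredQuantities,
    calibrate_linear,
    calibrate_sublinear,
)

# Measured quantities for intact cardiac rat cells at room temperature:
# isometric tension 120 kPa, attached fraction 0.22, v_max 8 1/s, v0 2 1/s.
# The fast-step stiffness is taken as 65 (the value consistent with the
# published calibrated rate constants r0 = 130 and 208 1/s).
TISO_PA = 120e3
MU0_ISO = 0.22
VMAX = 8.0
V0 = 2.0
K2 = 65.0


@pytest.fixture(scope="session")
def cardiac_measurements() -> MeasuredQuantities:
    return MeasuredQuantities(
        t_iso=TISO_PA, mu0_iso=MU0_ISO, v_max=VMAX, v0=V0, k2_tilde=K2
    )


@pytest.fixture(scope="session")
def linear_model(cardiac_measurements):
    """Calibrated linear-growth parameter set (r0=130, alpha=24.375, ...)."""
    return calibrate_linear(cardiac_measurements, P=1.0).params


@pytest.fixture(scope="session")
def sublinear_model(cardiac_measurements):
    """Calibrated sublinear-growth parameter set (r0=208, alpha=39, ...)."""
    return calibrate_sublinear(cardiac_measurements, P=1.0).params


@pytest.fixture(scope="session")
def huxley_params() -> HuxleyRateParams:
    """Skeletal-muscle rate constants of the classic two-state model."""
    return HuxleyRateParams(f1=65.0, g1=15.0, g2=313.5, h=10.0)


def random_admissible_measurements(rng: np.random.Generator) -> MeasuredQuantities:
    """Random draw of a physically admissible measurement vector."""
    v0 = rng.uniform(0.5, 5.0)
    v_max = v0 * rng.uniform(1.5, 10.0)
    return MeasuredQuantities(
        t_iso=rng.uniform(20e3, 300e3),
        mu0_iso=rng.uniform(0.05, 0.6),
        v_max=v_max,
        v0=v0,
        k2_tilde=rng.uniform(10.0, 120.0),
    )
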