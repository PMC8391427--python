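import numpy as np
import pytest
from hypothesis import settings

from frysim import (
    BoilingModel,
    EnthalpyConfig,
    FryingConditions,
    PropertySet,
    VSNConfig,
    simulate_enthalpy,
    simulate_vsn,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def props():
    return PropertySet()


@pytest.fixture(scope="session")
def cond():
    return FryingConditions()


@pytest.fixture(scope="session")
def fixed_boil():
    return BoilingModel()


@pytest.fixture(scope="session")
def variable_boil():
    return BoilingModel(mode="variable")


# the default-resolution runs are shared across many tests; computed once
@pytest.fixture(scope="session")
def vsn_fixed(props, cond, fixed_boil):
    return simulate_vsn(props, cond, fixed_boil, VSNConfig())


@pytest.fixture(scope="session")
def vsn_doubled(props, cond, fixed_boil):
    return simulate_vsn(props, cond, fixed_boil, VSNConfig(J=16))


@pytest.fixture(scope="session")
def ent_fixed(props, cond, fixed_boil):
    return simulate_enthalpy(props, cond, fixed_boil, EnthalpyConfig(N=50))


@pytest.fixture(scope="session")
def ent_doubled(props, cond, fixed_boil):
    return simulate_enthalpy(props, cond, fixed_boil, EnthalpyConfig(N=100))


@pytest.fixture(scope="session")
def ent_variable(props, cond, variable_boil):
    return simulate_enthalpy(props, cond, variable_boil, EnthalpyConfig(N=50))


@pytest.fixture(scope="session")
def ent_n30(props, cond, fixed_boil):
    return simulate_enthalpy(props, cond, fixed_boil, EnthalpyConfig(N=30))


@pytest.fixture(scope="session")
def ent_n60(props, cond, fixed_boil):
    return simulate_enthalpy(props, cond, fixed_boil, EnthalpyConfig(N=60))


def plateau_roughness(result):
    """RMS of the high-pass residual of the center trace across the plateau.

    Detrending with a wide smoothing window isolates the mesh-quantized
    micro-structure (one blip per node finishing its band crossing) from
    the slow plateau drift.
    """
    from scipy.signal import savgol_filter

    g = np.arange(100.0, result.events["completed_at"] - 10.0, 1.0)
    ct = result.center_history(g)
    resid = ct - savgol_filter(ct, 51, 3)
    return float(np.sqrt(np.mean(resid**2)))


def common_grid(a, b, step=1.0):
    """Time grid covering the overlap of two results."""
    return np.arange(0.0, min(a.times[-1], b.times[-1]), step)
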