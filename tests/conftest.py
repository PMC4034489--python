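import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gliomascale.fixtures import load_parameters
from gliomascale.network import NetworkConstants

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Published baseline reaction constants."""
    p, _ = load_parameters()
    return p


@pytest.fixture(scope="session")
def consts():
    return NetworkConstants()


@pytest.fixture(scope="session")
def gentle_params(params):
    """A mildly-sprung variant of the network for explicit integration tests.

    The published constants span five orders of magnitude in rate, which is
    exactly why the driver uses the steady-state coupling; for tests that
    exercise the explicit integrator against long-horizon behaviour we use a
    parameter set whose fastest and slowest rates are within ~2 decades, so
    a fixed RK4 substep can resolve the whole relaxation.
    """
    overrides = dict(
        k1=1.2e-9, k2=1e-3, k3=1.0, k4=0.1, k5=1.0, k6=0.1, k7=0.1, k8=0.1,
        k9=1e-3, k10=1.0, k11_c1=10.0, k11_c2=100.0, k12=1.0, k13_c1=1.0,
        k13_c2=100.0, k14=1.0, k15=1.0, k16=1.0, k17_c1=1.0, k17_c2=100.0,
        k18_c=1.0,
    )
    return dataclasses.replace(params, **overrides)


@pytest.fixture(scope="session")
def gentle_consts():
    return NetworkConstants(d4=0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
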