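import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crossinfo as ci

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params_a() -> ci.ModelParameters:
    return ci.set_a().params


@pytest.fixture(scope="session")
def params_b() -> ci.ModelParameters:
    return ci.set_b().params


@pytest.fixture(scope="session")
def generic_init() -> ci.StateVector:
    return ci.set_b().init


@pytest.fixture(scope="session")
def endemic_b(params_b) -> ci.EquilibriumPoint:
    """Interior equilibrium of the super-threshold parameter set."""
    return ci.find_endemic_equilibrium(params_b)


@pytest.fixture(scope="session")
def small_sigmas() -> ci.NoiseIntensities:
    return ci.NoiseIntensities.uniform(1e-4)
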