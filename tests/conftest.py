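import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from agepbpk import AgeSpec, DoseEvent, load_drug, make_individual, simulate

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ADULT_AGE = 39.0
IV_REGIMEN = (DoseEvent(route="iv_infusion", amount=0.75, start=0.0, duration=2.0 / 60.0),)
ORAL_REGIMEN = (DoseEvent(route="oral", amount=10.0, start=0.0),)


@pytest.fixture(scope="session")
def midazolam():
    return load_drug("midazolam")


@pytest.fixture(scope="session")
def alfentanil():
    return load_drug("alfentanil")


@pytest.fixture(scope="session")
def adult_individual(midazolam):
    return make_individual(AgeSpec(postnatal_age=ADULT_AGE), midazolam)


@pytest.fixture(scope="session")
def iv_regimen():
    return IV_REGIMEN


@pytest.fixture(scope="session")
def oral_regimen():
    return ORAL_REGIMEN


@pytest.fixture(scope="session")
def adult_iv_result(adult_individual, iv_regimen):
    return simulate(adult_individual, iv_regimen)


@pytest.fixture(scope="session")
def adult_oral_result(adult_individual, oral_regimen):
    return simulate(adult_individual, oral_regimen)


def quick_sim(individual, regimen, **kw):
    """Simulation with mildly relaxed tolerances for speed in tests that do
    not probe solver accuracy."""
    kw.setdefault("rtol", 1e-7)
    kw.setdefault("atol", 1e-9)
    return simulate(individual, regimen, **kw)
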