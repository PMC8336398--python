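import numpy as np
import pytest

from ahpfiscal import (
    AgeSchedule,
    FiscalParameters,
    LifeTable,
    ModelInputs,
)
from ahpfiscal.synthetic import default_fixture


@pytest.fixture(scope="session")
def params() -> FiscalParameters:
    return FiscalParameters()


@pytest.fixture(scope="session")
def fixture_country():
    """Calibrated synthetic Belgian-like country (shared across the suite)."""
    inputs, result = default_fixture()
    return inputs, result


@pytest.fixture(scope="session")
def fixture_inputs(fixture_country) -> ModelInputs:
    return fixture_country[0]


def flat_life_table(q: float = 0.0, max_age: int = 100) -> LifeTable:
    ages = np.arange(0, max_age + 1)
    qx = np.full(len(ages), q)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def flat_schedule(value: float, lo: int = 18, hi: int = 100) -> AgeSchedule:
    ages = np.arange(lo, hi + 1)
    return AgeSchedule(ages, np.full(len(ages), float(value)))


@pytest.fixture
def flat_inputs() -> ModelInputs:
    """Immortal country with flat profiles: closed-form annuity territory."""
    return ModelInputs(
        life_table=flat_life_table(0.0),
        earnings=flat_schedule(30_000.0),
        activity=flat_schedule(0.8),
        disability=flat_schedule(0.1),
        gp_health=flat_schedule(1_000.0),
        consumption=flat_schedule(5_000.0),
    )


@pytest.fixture
def zero_growth_params() -> FiscalParameters:
    """3% discounting only: no wage growth, indexation or health inflation."""
    return FiscalParameters(
        wage_growth=0.0, transfer_inflation=0.0, health_inflation=0.0
    )
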