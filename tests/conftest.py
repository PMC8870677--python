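import pytest

from alphalq import (
    LQParameters,
    OutcomeDataset,
    build_dose_table,
    builtin_arms,
    standard_scenarios,
)


@pytest.fixture(scope="session")
def params():
    return LQParameters()


@pytest.fixture(scope="session")
def arms():
    return builtin_arms()


@pytest.fixture(scope="session")
def scenarios(params):
    return standard_scenarios(params)


@pytest.fixture(scope="session")
def summaries_8gy(arms, scenarios):
    """Dose table for the single-fraction 8 Gy EBRT scenario."""
    return build_dose_table(arms, scenarios[0])


@pytest.fixture(scope="session")
def os_dataset(arms, summaries_8gy):
    return OutcomeDataset.from_arms(arms, summaries_8gy, "os_2y")


@pytest.fixture(scope="session")
def tox_dataset(arms, summaries_8gy):
    return OutcomeDataset.from_arms(arms, summaries_8gy, "tox")
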