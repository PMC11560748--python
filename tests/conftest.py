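import pytest

from soilsqi import ScenarioSpec, simulate_scenario


@pytest.fixture(scope="session")
def default_spec():
    return ScenarioSpec(seed=1)


@pytest.fixture(scope="session")
def simulated(default_spec):
    """One default-scenario realization shared across read-only tests."""
    chem, communities = simulate_scenario(default_spec)
    return chem, communities


@pytest.fixture(scope="session")
def chem(simulated):
    return simulated[0]


@pytest.fixture(scope="session")
def communities(simulated):
    return simulated[1]


@pytest.fixture(scope="session")
def flat_simulated():
    """Flat scenario: planted blocks are the only community structure."""
    spec = ScenarioSpec.flat(seed=3)
    return simulate_scenario(spec)
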