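import pytest

from wildemo.simulate import SimulationScenario, simulate_observation_set


@pytest.fixture(scope="session")
def default_scenario():
    return SimulationScenario(seed=7)


@pytest.fixture(scope="session")
def default_obs(default_scenario):
    """One validated synthetic observation set shared across tests."""
    data, truth = simulate_observation_set(default_scenario)
    return data, truth
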