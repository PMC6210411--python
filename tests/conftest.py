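import pytest

from gaitcycles import GaitScenario, generate_trial


@pytest.fixture(scope="session")
def noiseless_scenario() -> GaitScenario:
    return GaitScenario(noise_sd=0.0, n_cycles_per_side=5, seed=42)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_scenario):
    return generate_trial(noiseless_scenario)


@pytest.fixture(scope="session")
def noisy_trial():
    scenario = GaitScenario(noise_sd=0.2, n_cycles_per_side=5, seed=43)
    return generate_trial(scenario)
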