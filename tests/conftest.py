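import pytest

from parevo import ParallelEvolutionModel, SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_dataset():
    """One desk-scale simulated experiment, shared read-only across tests."""
    return simulate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fitted(default_dataset):
    """The default pipeline fitted to the shared experiment."""
    return ParallelEvolutionModel(default_dataset).fit()
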