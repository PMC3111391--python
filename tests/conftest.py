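import numpy as np
import pytest

from alienscan import PipelineConfig, SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def experiment():
    """One medium synthetic experiment shared across read-only tests."""
    return simulate_experiment(SimulationConfig(n_genes=60, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
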