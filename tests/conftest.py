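import numpy as np
import pytest
from hypothesis import settings

from nervering.core import ConnectivityMatrix, Neuron, Roster
from nervering.synthetic import EnsembleSpec, gen_stage_ensemble

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_roster():
    return Roster(
        [
            Neuron("AL", "sensory", "A"),
            Neuron("AR", "sensory", "A"),
            Neuron("BL", "inter", "B"),
            Neuron("BR", "inter", "B"),
            Neuron("C", "motor", None),
            Neuron("D", "motor", None),
        ]
    )


@pytest.fixture(scope="session")
def default_ensemble():
    """Default-condition synthetic ensemble, shared across tests."""
    return gen_stage_ensemble(EnsembleSpec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(roster, rng, density=0.3, stage=""):
    n = len(roster)
    W = (rng.random((n, n)) < density) * rng.random((n, n))
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(roster, W, stage=stage)
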