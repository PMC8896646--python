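import numpy as np
import pytest

from caconet.graph_dataset import CorrelationNetwork
from caconet.io_otu import OtuTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """10 samples x 6 taxa raw-count table with binary labels."""
    counts = rng.integers(0, 200, size=(10, 6)).astype(float)
    counts[counts < 20] = 0.0
    counts[:, 0] += 1.0  # guarantee nonzero row sums
    return OtuTable(
        sample_ids=[f"s{i}" for i in range(10)],
        taxon_ids=[f"t{j}" for j in range(6)],
        abundance=counts,
        labels=np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1]),
    )


def random_network(rng, p=5, label=0, scale=0.5):
    A = rng.uniform(-scale, scale, size=(p, p))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    return CorrelationNetwork([f"t{j}" for j in range(p)], A, label)


@pytest.fixture
def network_factory(rng):
    def make(p=5, label=0, scale=0.5):
        return random_network(rng, p, label, scale)

    return make
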