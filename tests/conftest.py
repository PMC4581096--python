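import numpy as np
import pytest

from bnggm import (
    BGeScorer,
    DAG,
    Dataset,
    GaussianSimConfig,
    benchmark_dag,
    simulate_gaussian,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain3():
    """A -> B -> C chain on three nodes."""
    adj = np.zeros((3, 3), dtype=np.int8)
    adj[0, 1] = 1
    adj[1, 2] = 1
    return DAG(adj, ["A", "B", "C"])


@pytest.fixture
def gauss3(chain3):
    """100 observations simulated from the 3-node chain at sigma^2 = 0.01."""
    return simulate_gaussian(chain3, GaussianSimConfig(seed=7))


@pytest.fixture
def scorer3(gauss3):
    return BGeScorer(gauss3)


@pytest.fixture
def bench10():
    return benchmark_dag()


@pytest.fixture
def dataset_random(rng):
    """Unstructured 4-variable data for property tests."""
    return Dataset(rng.normal(size=(40, 4)))
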