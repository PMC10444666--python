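import numpy as np
import pytest

import mptml


@pytest.fixture(scope="session")
def pair_model():
    return mptml.pair_clustering_model()


@pytest.fixture(scope="session")
def bernoulli_model():
    """One tree, two categories, a single success parameter."""
    return mptml.parse_eqn("t yes p\nt no (1-p)")


@pytest.fixture(scope="session")
def two_tree_model():
    """Two independent Bernoulli trees (R=2 when both parameters random)."""
    return mptml.parse_eqn("t1 a p\nt1 b (1-p)\nt2 c q\nt2 d (1-q)")


@pytest.fixture(scope="session")
def pair_theta():
    return np.array([0.5, 0.4, 0.25, 0.15])


@pytest.fixture(scope="session")
def small_pair_dataset(pair_model):
    """A small simulated pair-clustering sample shared across tests."""
    pop = mptml.default_population(T=30, counts_per_system=(60, 15), seed=123)
    data, truth = mptml.simulate_dataset(pop)
    return pop, data, truth
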