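import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from connebm import WeightedConnectome, normalize_weights

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    """Unit-weight triangle."""
    W = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    return WeightedConnectome(["a", "b", "c"], W)


@pytest.fixture
def two_cliques():
    """Two 5-node cliques joined by one weak edge."""
    W = np.zeros((10, 10))
    for block in (range(5), range(5, 10)):
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = 1.0
    W[4, 5] = W[5, 4] = 0.1
    return normalize_weights(WeightedConnectome([f"n{i}" for i in range(10)], W))


@pytest.fixture
def random_connectome(rng):
    from oracles import random_normalized_graph

    W = random_normalized_graph(rng, n_min=8, n_max=8)
    return WeightedConnectome([f"r{i}" for i in range(8)], W)
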