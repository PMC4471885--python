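import numpy as np
import pytest

from netrecon.graph import Network, from_edges
from netrecon.generators import generate_ws
from netrecon.simulate import SimulationParams, run_spreading


@pytest.fixture
def triangle():
    return Network(n_nodes=3, links=frozenset({(0, 1), (0, 2), (1, 2)}))


@pytest.fixture
def path4():
    """Path 0-1-2-3."""
    return Network(n_nodes=4, links=frozenset({(0, 1), (1, 2), (2, 3)}))


@pytest.fixture
def star():
    """Star with center 0 and 10 leaves."""
    return from_edges([(0, i) for i in range(1, 11)], n_nodes=11)


def random_network(rng: np.random.Generator, n_max: int = 30) -> Network:
    """A random connected-ish simple network for property tests."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.1, 0.5))
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p]
    edges += [(i, i + 1) for i in range(n - 1)]  # keep it connected
    return from_edges(edges, n_nodes=n)


def random_record(rng: np.random.Generator, n_max: int = 30):
    """(network, spreading record) pair drawn from the simulator itself."""
    net = random_network(rng, n_max)
    params = SimulationParams(
        submission_prob=float(rng.uniform(0.3, 1.0)),
        infection_rate=float(rng.uniform(0.05, 0.9)),
        seed=int(rng.integers(0, 2**31)),
    )
    return net, run_spreading(net, params)


@pytest.fixture(scope="session")
def ws_pipeline():
    """One full spreading experiment on a small-world network."""
    net = generate_ws(100, 10, 0.1, seed=42)
    record = run_spreading(net, SimulationParams(0.5, 0.2, seed=7))
    return net, record
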