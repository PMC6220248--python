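import numpy as np
import pytest

from netrait import BinaryNetwork, RegionTable, WeightedConnectome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def regions10():
    return RegionTable.from_names([f"r{i}" for i in range(10)])


def random_connectome(n_nodes, rng, density=0.5, subject_id="sub"):
    """A valid random weighted connectome for round-trip / property tests."""
    w = np.zeros((n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, k=1)
    mask = rng.random(len(iu)) < density
    vals = rng.lognormal(0.0, 1.0, size=mask.sum())
    w[iu[mask], ju[mask]] = vals
    w = w + w.T
    regions = RegionTable.from_names([f"r{i}" for i in range(n_nodes)])
    return WeightedConnectome(subject_id=subject_id, weights=w,
                              regions=regions)


def random_binary_network(n_nodes, rng, p=0.4):
    iu, ju = np.triu_indices(n_nodes, k=1)
    mask = rng.random(len(iu)) < p
    edges = frozenset((int(i), int(j))
                      for i, j in zip(iu[mask], ju[mask]))
    return BinaryNetwork(n_nodes=n_nodes, edges=edges)
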