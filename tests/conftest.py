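import numpy as np
import pytest

from neurograph.nodes import load_node_table
from neurograph.synthetic_cohort import GeneratorConfig


@pytest.fixture(scope="session")
def node_names():
    return load_node_table().names


@pytest.fixture(scope="session")
def default_cfg():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced cohort for fast end-to-end paths."""
    return GeneratorConfig(n_patients=12, n_controls=10, seed=7)


def adjacency_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return a


@pytest.fixture(scope="session")
def make_adjacency():
    return adjacency_from_edges


@pytest.fixture
def random_graphs():
    """Seeded random graphs of varied size/density for oracle comparisons."""

    def _make(n_graphs, max_n=30, seed=0):
        rng = np.random.default_rng(seed)
        graphs = []
        for _ in range(n_graphs):
            n = int(rng.integers(5, max_n + 1))
            p = float(rng.uniform(0.1, 0.6))
            a = rng.random((n, n)) < p
            a = np.triu(a, 1)
            graphs.append(a | a.T)
        return graphs

    return _make
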