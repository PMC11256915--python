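import networkx as nx
import numpy as np
import pytest

from spatialcompare.graphs import SpatialGraph


def graph_from_networkx(g: nx.Graph) -> SpatialGraph:
    mapping = {v: i for i, v in enumerate(sorted(g.nodes))}
    edges = np.array(
        [(mapping[u], mapping[v]) for u, v in g.edges], dtype=np.int64
    ).reshape(-1, 2)
    return SpatialGraph(n_nodes=g.number_of_nodes(), edges=edges)


def random_graph(rng: np.random.Generator, n_max: int = 30) -> SpatialGraph:
    """Random (possibly disconnected) graph with >= 1 node."""
    n = int(rng.integers(1, n_max + 1))
    p = float(rng.uniform(0.05, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return graph_from_networkx(g)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def path4():
    """4-node path 0-1-2-3."""
    return SpatialGraph(n_nodes=4, edges=np.array([[0, 1], [1, 2], [2, 3]]))


@pytest.fixture
def triangle():
    return SpatialGraph(n_nodes=3, edges=np.array([[0, 1], [1, 2], [0, 2]]))


@pytest.fixture
def small_dataset():
    """Tiny 2-condition dataset for I/O and plumbing tests."""
    from spatialcompare.synthetic import SynthSpec, generate_dataset

    spec = SynthSpec(
        seed=7,
        n_cells=40,
        n_types=3,
        expression_dim=4,
        n_samples_per_condition={"A": 2, "B": 2},
    )
    return generate_dataset(spec)
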