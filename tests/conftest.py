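import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rsfcnet.connectivity import ThresholdedGraph, WeightMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weight_matrix(n: int, rng: np.random.Generator) -> WeightMatrix:
    w = rng.random((n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w, node_ids=[f"n{i}" for i in range(n)])


def graph_from_adjacency(adj: np.ndarray, cost: float = 0.1) -> ThresholdedGraph:
    adj = np.asarray(adj, dtype=float)
    return ThresholdedGraph(
        adj, cost=cost, mode="binary", node_ids=[f"n{i}" for i in range(adj.shape[0])]
    )


def random_connected_adjacency(n: int, rng: np.random.Generator, p: float = 0.3) -> np.ndarray:
    """Random graph made connected by threading a random spanning path."""
    adj = (rng.random((n, n)) < p).astype(float)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    order = rng.permutation(n)
    for a, b in zip(order, order[1:]):
        adj[a, b] = adj[b, a] = 1.0
    return adj
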