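"""Weight-matrix construction and MST-backbone network thresholding.

The association weight between two nodes is the absolute Fisher z-transform of
their Pearson correlation.  Thresholding at a target cost (fraction of the
n(n-1)/2 possible edges retained) proceeds in two stages: a maximum-weight
spanning tree guarantees a connected backbone with no isolated node, then the
remaining edges are added in descending weight order until the edge count
matches the cost.  Because the backbone is fixed and growth is a prefix of one
deterministic edge ranking, the graphs of a cost sweep are nested and every
graph is connected at every feasible cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .synthetic import TimeSeriesMatrix

DEFAULT_COSTS = [round(c, 2) for c in np.arange(0.03, 0.401, 0.01)]
GROUP_LEVEL_COST = 0.03


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("correlation matrix must be symmetric")


@dataclass
class WeightMatrix:
    """Symmetric nonnegative association matrix (|Fisher z|), zero diagonal."""

    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("weights must be finite and nonnegative")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("weight matrix diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ThresholdedGraph:
    """Connected graph at a given cost, binary or weighted, exact edge count."""

    adjacency: np.ndarray
    cost: float
    mode: str
    node_ids: list[str]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return set(zip(i.tolist(), j.tolist()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        if self.mode == "weighted":
            g.add_weighted_edges_from(
                zip(i.tolist(), j.tolist(), self.adjacency[i, j].tolist())
            )
        else:
            g.add_edges_from(zip(i.tolist(), j.tolist()))
        return g


def correlation_matrix(ts: TimeSeriesMatrix) -> CorrelationMatrix:
    """Pearson correlation of every pair of node time series."""
    sd = ts.values.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [ts.node_ids[i] for i in zero]
        raise ValueError(f"zero-variance time series for node(s): {names}")
    r = np.corrcoef(ts.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, node_ids=list(ts.node_ids))


def to_weight_matrix(corr: CorrelationMatrix) -> WeightMatrix:
    """Edge weights |atanh(r)|: rectified Fisher r-to-z transform."""
    r = corr.values.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise ValueError("off-diagonal |r| = 1 gives an infinite weight")
    w = np.abs(np.arctanh(r, where=off, out=np.zeros_like(r)))
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return WeightMatrix(w, node_ids=list(corr.node_ids))


def edges_for_cost(n_nodes: int, cost: float) -> int:
    """Number of edges for a target cost: round(cost * n(n-1)/2), half up."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    n_pairs = n_nodes * (n_nodes - 1) // 2
    k = int(np.floor(cost * n_pairs + 0.5))
    if k < n_nodes - 1:
        min_cost = (n_nodes - 1) / n_pairs
        raise ValueError(
            f"cost {cost} cannot fit the spanning backbone; "
            f"minimum feasible cost is {min_cost:.4g}"
        )
    if k > n_pairs:
        raise ValueError(f"cost {cost} exceeds the complete graph")
    return k


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _edge_selection_order(weights: WeightMatrix) -> list[tuple[int, int]]:
    """Deterministic edge ranking: backbone tree edges first, then the rest.

    Edges are sorted by descending weight with ties broken lexicographically on
    (smaller index, larger index).  Kruskal on that order yields the
    maximum-weight spanning tree; tree edges are emitted in their sorted order,
    followed by all non-tree edges in sorted order.  Any cost-c graph is then a
    prefix of this list, which makes sweeps nested by construction.
    """
    n = weights.n_nodes
    iu, ju = np.triu_indices(n, 1)
    w = weights.values[iu, ju]
    order = np.lexsort((ju, iu, -w))
    uf = _UnionFind(n)
    tree: list[tuple[int, int]] = []
    rest: list[tuple[int, int]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            tree.append((i, j))
        else:
            rest.append((i, j))
    return tree + rest


def mst_threshold(weights: WeightMatrix, cost: float, mode: str = "binary") -> ThresholdedGraph:
    """Threshold a weight matrix to a connected graph at the given cost.

    A maximum-weight spanning tree forms the backbone (every node reaches every
    other; no island), then edges are added in descending weight order until
    the edge count equals ``edges_for_cost``.  In binary mode retained entries
    are 1; in weighted mode they keep the source weights.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError(f"mode must be 'binary' or 'weighted', got {mode!r}")
    k = edges_for_cost(weights.n_nodes, cost)
    selection = _edge_selection_order(weights)[:k]
    return _graph_from_edges(weights, selection, cost, mode)


def _graph_from_edges(
    weights: WeightMatrix, edges: list[tuple[int, int]], cost: float, mode: str
) -> ThresholdedGraph:
    n = weights.n_nodes
    adj = np.zeros((n, n))
    idx = np.asarray(edges)
    if mode == "weighted":
        vals = weights.values[idx[:, 0], idx[:, 1]]
    else:
        vals = np.ones(len(edges))
    adj[idx[:, 0], idx[:, 1]] = vals
    adj[idx[:, 1], idx[:, 0]] = vals
    return ThresholdedGraph(adj, cost=cost, mode=mode, node_ids=list(weights.node_ids))


def cost_sweep(
    weights: WeightMatrix, costs: list[float] | None = None, mode: str = "binary"
) -> list[ThresholdedGraph]:
    """Threshold at every cost of an ascending grid (default 0.03..0.40 step 0.01).

    The edge ranking is computed once, so the sweep's edge sets are nested:
    the graph at a lower cost is a subgraph of every higher-cost graph.
    """
    if costs is None:
        costs = DEFAULT_COSTS
    if any(b <= a for a, b in zip(costs, costs[1:])):
        raise ValueError("costs must be sorted strictly ascending")
    selection = _edge_selection_order(weights)
    graphs = []
    for cost in costs:
        k = edges_for_cost(weights.n_nodes, cost)
        graphs.append(_graph_from_edges(weights, selection[:k], cost, mode))
    return graphs


def weight_matrix_from_timeseries(ts: TimeSeriesMatrix) -> WeightMatrix:
    """Convenience composition: Pearson r -> |Fisher z| weights."""
    return to_weight_matrix(correlation_matrix(ts))
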