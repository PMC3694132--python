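"""Small-world and efficiency metrics with random/regular reference networks.

Definitions follow the standard graph-theory literature: clustering
coefficient Cp and characteristic path length Lp (Watts-Strogatz), global and
local efficiency (Latora-Marchiori), and small-worldness sigma as the ratio of
normalized clustering to normalized path length against degree-preserving
random references (Humphries-Gurney).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ThresholdedGraph


@dataclass
class MetricSet:
    Cp: float
    Lp: float
    Eglobal: float
    Elocal: float
    sigma: float | None = None


def _as_nx(g: ThresholdedGraph | nx.Graph) -> nx.Graph:
    if isinstance(g, ThresholdedGraph):
        return g.to_networkx()
    return g


def _binary_adjacency(g: ThresholdedGraph | nx.Graph) -> np.ndarray:
    if isinstance(g, ThresholdedGraph):
        adj = (g.adjacency > 0).astype(float)
    else:
        adj = (nx.to_numpy_array(g) > 0).astype(float)
    return adj


def _distances(adj: np.ndarray) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def _mean_clustering(adj: np.ndarray) -> float:
    degree = adj.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", adj, adj, adj) / 2.0
    denom = degree * (degree - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return float(local.mean())


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def smallworld_metrics(g: ThresholdedGraph | nx.Graph) -> tuple[float, float]:
    """Clustering coefficient Cp and characteristic path length Lp.

    Cp averages, over nodes, the fraction of closed triangles among the
    node's neighbor pairs (0 for degree < 2).  Lp is the mean shortest-path
    length over all unordered node pairs; it requires a connected graph.
    """
    adj = _binary_adjacency(g)
    if adj.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    dist = _distances(adj)
    if not np.all(np.isfinite(dist)):
        raise ValueError("characteristic path length is defined only on connected graphs")
    n = adj.shape[0]
    lp = dist.sum() / (n * (n - 1))
    return _mean_clustering(adj), float(lp)


def efficiency(g: ThresholdedGraph | nx.Graph) -> tuple[float, float]:
    """Global and local efficiency.

    Eglobal is the mean of 1/d(i,j) over pairs (0 for unreachable pairs);
    Elocal averages, over nodes, the global efficiency of the subgraph induced
    by the node's neighbors (0 for fewer than 2 neighbors).
    """
    adj = _binary_adjacency(g)
    eglobal = _global_efficiency(adj)
    locals_ = []
    for i in range(adj.shape[0]):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            locals_.append(0.0)
            continue
        locals_.append(_global_efficiency(adj[np.ix_(nbrs, nbrs)]))
    return eglobal, float(np.mean(locals_))


def ring_lattice(n_nodes: int, n_edges: int) -> nx.Graph:
    """Regular ring lattice with exactly ``n_edges`` edges.

    Edges are assigned ring by ring of increasing circular distance (distance
    1 first, then 2, ...); a partially filled ring takes its edges in node
    order, so every node's degree differs by at most one within the last ring.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise ValueError("n_edges out of range")
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    remaining = n_edges
    for dist in range(1, n_nodes // 2 + 1):
        ring = [
            (i, (i + dist) % n_nodes)
            for i in range(n_nodes if (dist < n_nodes / 2) else n_nodes // 2)
        ]
        for i, j in ring[:remaining]:
            g.add_edge(i, j)
        remaining -= min(remaining, len(ring))
        if remaining == 0:
            break
    return g


def reference_networks(
    g: ThresholdedGraph | nx.Graph, n_random: int = 20, seed: int = 0
) -> tuple[list[nx.Graph], nx.Graph]:
    """Degree-preserving random rewirings and a matched regular lattice.

    Each random reference applies 10 * |E| connectedness-preserving double
    edge swaps, so its degree sequence equals the input's exactly.  The
    regular reference is a ring lattice with the same node and edge counts.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    graph = _as_nx(g)
    m = graph.number_of_edges()
    randoms = []
    for k in range(n_random):
        r = graph.copy()
        # nx raises if a graph is too small/dense to swap; keep the copy then
        try:
            nx.connected_double_edge_swap(r, nswap=10 * m, seed=seed + k)
        except nx.NetworkXError:
            pass
        randoms.append(r)
    lattice = ring_lattice(graph.number_of_nodes(), m)
    return randoms, lattice


def small_worldness(g: ThresholdedGraph | nx.Graph, random_refs: list[nx.Graph]) -> float:
    """Sigma = (Cp / <Cp_random>) / (Lp / <Lp_random>)."""
    if not random_refs:
        raise ValueError("need at least one random reference network")
    cp, lp = smallworld_metrics(g)
    cps, lps = zip(*(smallworld_metrics(r) for r in random_refs))
    mean_cp = float(np.mean(cps))
    if mean_cp == 0:
        raise ValueError("mean random clustering coefficient is zero")
    return (cp / mean_cp) / (lp / float(np.mean(lps)))


def metric_set(
    g: ThresholdedGraph | nx.Graph,
    n_random: int | None = None,
    seed: int = 0,
) -> MetricSet:
    """All four metrics, plus sigma when ``n_random`` is given."""
    cp, lp = smallworld_metrics(g)
    eg, el = efficiency(g)
    sigma = None
    if n_random:
        randoms, _ = reference_networks(g, n_random=n_random, seed=seed)
        sigma = small_worldness(g, randoms)
    return MetricSet(Cp=cp, Lp=lp, Eglobal=eg, Elocal=el, sigma=sigma)


METRIC_NAMES = ["Cp", "Lp", "Eglobal", "Elocal"]


def metric_curves(
    graphs: dict[str, list[list[ThresholdedGraph]]],
    n_random: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject metric values over a common cost grid.

    ``graphs`` maps group name -> per-subject lists of thresholded graphs (one
    per cost, same grid for everyone).  Returns a tidy DataFrame with columns
    group, subject, cost, Cp, Lp, Eglobal, Elocal (and sigma if requested).
    """
    grids = {
        tuple(g.cost for g in subject)
        for subjects in graphs.values()
        for subject in subjects
    }
    if len(grids) > 1:
        raise ValueError("all subjects must share a common cost grid")
    rows = []
    for group, subjects in graphs.items():
        for si, subject in enumerate(subjects):
            for g in subject:
                ms = metric_set(g, n_random=n_random, seed=seed)
                row = {
                    "group": group,
                    "subject": si,
                    "cost": g.cost,
                    "Cp": ms.Cp,
                    "Lp": ms.Lp,
                    "Eglobal": ms.Eglobal,
                    "Elocal": ms.Elocal,
                }
                if ms.sigma is not None:
                    row["sigma"] = ms.sigma
                rows.append(row)
    return pd.DataFrame(rows)


def group_curve_summary(curves: pd.DataFrame) -> pd.DataFrame:
    """Group mean and SEM of every metric at every cost."""
    metrics = [c for c in curves.columns if c not in ("group", "subject", "cost")]
    agg = curves.groupby(["group", "cost"])[metrics].agg(["mean", "sem"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
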