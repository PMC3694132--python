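"""Independent brute-force oracles used to validate the graph metrics.

Everything here is deliberately naive: Floyd-Warshall over the dense
adjacency, explicit triangle counting, and pair enumeration for the
efficiencies.  None of it shares code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def clustering_coefficient(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        k = nbrs.size
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b] > 0
        )
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals))


def characteristic_path_length(adj: np.ndarray) -> float:
    dist = floyd_warshall(adj)
    n = adj.shape[0]
    pairs = [dist[i, j] for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(pairs))


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = floyd_warshall(adj)
    inv = [1.0 / dist[i, j] if np.isfinite(dist[i, j]) and dist[i, j] > 0 else 0.0
           for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(inv))


def local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        if nbrs.size < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals.append(global_efficiency(sub))
    return float(np.mean(vals))


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def partition_to_labels(blocks: list[list[int]], n: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for module_id, block in enumerate(blocks, start=1):
        for item in block:
            labels[item] = module_id
    return labels
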