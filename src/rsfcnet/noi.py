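"""Per-node tests of group difference in functional community membership.

For a node of interest (NOI), each subject is summarized by a binary vector
over the remaining nodes: 1 where the other node shares the NOI's module, 0
where it does not.  Subject-pair similarity is the phi coefficient (Pearson
correlation of the two 0/1 vectors).  The scan tests, for every node, whether
mean within-group phi exceeds mean between-group phi, by permuting group
membership; one shared shuffle sequence is reused across all node tests so the
full scan is deterministic given its seed.  Significance is reported both
uncorrected and Bonferroni-corrected at alpha / n_nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modules import Partition, generate_group_permutations


@dataclass
class NoiScanResult:
    table: pd.DataFrame  # node, observed, p, significant_corrected, significant_uncorrected
    alpha: float
    n_nodes_tested: int
    n_permutations: int

    @property
    def corrected_alpha(self) -> float:
        return self.alpha / self.n_nodes_tested

    def significant_nodes(self, corrected: bool = True) -> list:
        col = "significant_corrected" if corrected else "significant_uncorrected"
        return self.table.loc[self.table[col], "node"].tolist()


def comodule_indicator(p: Partition, noi) -> np.ndarray:
    """Binary vector over the other nodes: 1 = shares the NOI's module.

    ``noi`` is a node id (if the partition carries node_ids) or an index.
    Entries follow the canonical node order with the NOI itself removed.
    """
    if isinstance(noi, (int, np.integer)):
        idx = int(noi)
        if not (0 <= idx < p.n_nodes):
            raise ValueError(f"node index {noi} out of range")
    else:
        if p.node_ids is None or noi not in p.node_ids:
            raise ValueError(f"unknown node of interest: {noi!r}")
        idx = p.node_ids.index(noi)
    same = (p.labels == p.labels[idx]).astype(int)
    return np.delete(same, idx)


def phi(x: np.ndarray, y: np.ndarray) -> float:
    """Phi coefficient: Pearson correlation of two dichotomous vectors.

    If either vector has zero variance the correlation is undefined; identical
    vectors return 1.0, otherwise NaN (callers exclude NaN pairs from means).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need vectors of length >= 2")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 1.0 if np.array_equal(x, y) else float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _pairwise_phi(indicators: np.ndarray) -> np.ndarray:
    """Subject x subject phi matrix for one node's indicator vectors."""
    n = indicators.shape[0]
    centered = indicators - indicators.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    cov = centered @ centered.T / indicators.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    # undefined pairs: zero-variance vector involved; identical vectors -> 1
    zero = sd == 0
    if zero.any():
        for i in np.flatnonzero(zero):
            for j in range(n):
                same = np.array_equal(indicators[i], indicators[j])
                corr[i, j] = corr[j, i] = 1.0 if same else np.nan
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def noi_scan(
    partitions_a: list[Partition],
    partitions_b: list[Partition],
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> NoiScanResult:
    """Permutation scan of every node's co-module similarity between groups.

    For each node: observed statistic = mean within-group phi minus mean
    between-group phi over subject pairs (pairs with undefined phi excluded);
    one-sided add-one p-value against shuffled group memberships.  The same
    shuffles are used for every node.  Bonferroni flags use alpha / n_nodes.
    """
    n_a, n_b = len(partitions_a), len(partitions_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 subjects")
    pooled = list(partitions_a) + list(partitions_b)
    n_nodes = pooled[0].n_nodes
    if any(p.n_nodes != n_nodes for p in pooled):
        raise ValueError("all partitions must cover the same node set")
    n = n_a + n_b
    node_ids = pooled[0].node_ids or list(range(n_nodes))

    # phi matrices per node, flattened over the n(n-1)/2 subject pairs
    iu, ju = np.triu_indices(n, 1)
    phi_flat = np.empty((n_nodes, iu.size))
    for v in range(n_nodes):
        indicators = np.stack([comodule_indicator(p, v) for p in pooled])
        phi_flat[v] = _pairwise_phi(indicators)[iu, ju]
    valid = ~np.isnan(phi_flat)
    phi_filled = np.where(valid, phi_flat, 0.0)

    perms = generate_group_permutations(n, n_a, n_permutations, seed)
    in_a = np.zeros(n, dtype=bool)
    in_a[:n_a] = True
    masks = np.vstack([in_a, perms])  # row 0 = observed labeling
    same_group = masks[:, iu] == masks[:, ju]  # (1+n_perm) x n_pairs

    # within/between means per node per labeling via two matrix products
    w = same_group.T.astype(float)
    b = (~same_group).T.astype(float)
    stats = (phi_filled @ w) / (valid @ w) - (phi_filled @ b) / (valid @ b)
    observed = stats[:, 0]
    null = stats[:, 1:]
    p_values = (1 + np.sum(null >= observed[:, None], axis=1)) / (1 + n_permutations)

    corrected_alpha = alpha / n_nodes
    table = pd.DataFrame(
        {
            "node": node_ids,
            "observed": observed,
            "p": p_values,
            "significant_corrected": p_values < corrected_alpha,
            "significant_uncorrected": p_values < alpha,
            "n_excluded_pairs": (~valid).sum(axis=1),
        }
    )
    return NoiScanResult(
        table=table,
        alpha=alpha,
        n_nodes_tested=n_nodes,
        n_permutations=n_permutations,
    )
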