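"""Modular decomposition and between-group comparison of modular architecture.

Partitions come from Louvain modularity maximization (best of several seeded
restarts).  Partition similarity is normalized mutual information (NMI,
arithmetic-mean normalization).  The group comparison is a permutation test of
the statistic

    mean pairwise similarity within groups  -  mean pairwise similarity between groups

with the null built by shuffling the pooled group memberships, preserving the
group sizes.  Consensus maps are built by matching every subject's module
labels to a representative subject (the one most similar on average to the
rest) with an optimal assignment on the label contingency table, then taking
the per-node modal label and its frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .connectivity import ThresholdedGraph


@dataclass
class Partition:
    """Node -> module labeling with the modularity Q of its source graph."""

    labels: np.ndarray  # positive integer module id per node, canonical order
    Q: float = np.nan
    node_ids: list[str] | None = None
    graph_ref: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    def module_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class SimilarityTestResult:
    observed: float
    null_values: np.ndarray
    p: float
    n_permutations: int
    within_mean_a: float = np.nan
    within_mean_b: float = np.nan
    between_mean: float = np.nan


@dataclass
class ConsensusPartition:
    labels: np.ndarray  # modal module id per node
    frequency: np.ndarray  # fraction of subjects with the modal label
    node_ids: list[str] | None = None


def detect_partition(
    g: ThresholdedGraph | nx.Graph,
    seed: int = 0,
    n_restarts: int = 20,
    weight: str | None = None,
) -> Partition:
    """Louvain community detection, best of ``n_restarts`` by modularity Q.

    Pass ``weight="weight"`` to maximize weighted modularity on a weighted
    graph; the default treats every retained edge as unit weight.
    """
    if isinstance(g, ThresholdedGraph):
        if weight is None and g.mode == "weighted":
            weight = "weight"
        graph = g.to_networkx()
    else:
        graph = g
    best_q = -np.inf
    best: list[set] | None = None
    for k in range(n_restarts):
        communities = nx.community.louvain_communities(graph, weight=weight, seed=seed + k)
        q = nx.community.modularity(graph, communities, weight=weight)
        if q > best_q:
            best_q, best = q, communities
    labels = np.empty(graph.number_of_nodes(), dtype=int)
    for module_id, members in enumerate(best, start=1):
        for node in members:
            labels[node] = module_id
    node_ids = g.node_ids if isinstance(g, ThresholdedGraph) else None
    return Partition(labels=labels, Q=float(best_q), node_ids=node_ids)


def count_major_modules(p: Partition, min_size: int = 6) -> int:
    """Number of modules with at least ``min_size`` member nodes."""
    return sum(1 for size in p.module_sizes().values() if size >= min_size)


def _nmi_from_codes(ca: np.ndarray, ka: int, cb: np.ndarray, kb: int) -> float:
    """NMI from 0-based module codes; ka/kb are the module counts."""
    if ka == 1 and kb == 1:
        return 1.0
    if ka == 1 or kb == 1:
        return 0.0
    n = ca.size
    cont = np.bincount(ca * kb + cb, minlength=ka * kb).astype(float) / n
    pa = np.bincount(ca, minlength=ka).astype(float) / n
    pb = np.bincount(cb, minlength=kb).astype(float) / n
    nz = cont > 0
    outer = np.outer(pa, pb).ravel()
    mi = float(np.sum(cont[nz] * np.log(cont[nz] / outer[nz])))
    ha = -float(np.sum(pa[pa > 0] * np.log(pa[pa > 0])))
    hb = -float(np.sum(pb[pb > 0] * np.log(pb[pb > 0])))
    return min(1.0, max(0.0, 2.0 * mi / (ha + hb)))


def _codes(labels: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, inv = np.unique(labels, return_inverse=True)
    return inv, uniq.size


def nmi(pa: Partition | np.ndarray, pb: Partition | np.ndarray) -> float:
    """Normalized mutual information of two partitions of the same node set.

    2*I(A;B) / (H(A)+H(B)) with natural logs and arithmetic-mean
    normalization; 1 when both partitions are a single module, 0 when exactly
    one is (an uninformative comparison).
    """
    la = pa.labels if isinstance(pa, Partition) else np.asarray(pa)
    lb = pb.labels if isinstance(pb, Partition) else np.asarray(pb)
    if la.shape != lb.shape:
        raise ValueError(f"partitions cover different node sets: {la.shape} vs {lb.shape}")
    ca, ka = _codes(la)
    cb, kb = _codes(lb)
    return _nmi_from_codes(ca, ka, cb, kb)


def pairwise_similarity_matrix(partitions: list[Partition]) -> np.ndarray:
    """Symmetric matrix of pairwise NMI values (unit diagonal)."""
    n = len(partitions)
    coded = [_codes(p.labels) for p in partitions]
    s = np.eye(n)
    for i in range(n):
        ca, ka = coded[i]
        for j in range(i + 1, n):
            cb, kb = coded[j]
            s[i, j] = s[j, i] = _nmi_from_codes(ca, ka, cb, kb)
    return s


def within_between_statistic(
    similarity: np.ndarray, in_group_a: np.ndarray
) -> tuple[float, float, float, float]:
    """(within - between, within_A mean, within_B mean, between mean).

    ``within`` pools the within-A and within-B pairs into a single mean.
    """
    a = np.asarray(in_group_a, dtype=bool)
    iu, ju = np.triu_indices(similarity.shape[0], 1)
    vals = similarity[iu, ju]
    same = a[iu] == a[ju]
    both_a = a[iu] & a[ju]
    both_b = ~a[iu] & ~a[ju]
    valid = ~np.isnan(vals)
    def _mean(mask):
        m = mask & valid
        return float(vals[m].mean()) if m.any() else np.nan
    within = _mean(same)
    between = _mean(~same)
    return within - between, _mean(both_a), _mean(both_b), between


def _permutation_pvalue(observed: float, null_values: np.ndarray) -> float:
    return float((1 + np.sum(null_values >= observed)) / (1 + null_values.size))


def permutation_test_from_similarity(
    similarity: np.ndarray,
    n_a: int,
    n_permutations: int = 10000,
    seed: int = 0,
    permutations: np.ndarray | None = None,
) -> SimilarityTestResult:
    """Group-membership permutation test on a precomputed similarity matrix.

    The first ``n_a`` rows are group A.  ``permutations`` (boolean matrix,
    one shuffled group-A mask per row) may be supplied to reuse one shuffle
    sequence across several tests; otherwise it is drawn from ``seed``.
    """
    n = similarity.shape[0]
    if not (2 <= n_a <= n - 2):
        raise ValueError("each group needs at least 2 subjects")
    in_a = np.zeros(n, dtype=bool)
    in_a[:n_a] = True
    observed, wa, wb, bt = within_between_statistic(similarity, in_a)
    if permutations is None:
        permutations = generate_group_permutations(n, n_a, n_permutations, seed)
    # vectorized within-minus-between over all shuffles at once
    iu, ju = np.triu_indices(n, 1)
    vals = similarity[iu, ju]
    valid = ~np.isnan(vals)
    filled = np.where(valid, vals, 0.0)
    same = permutations[:, iu] == permutations[:, ju]  # n_perm x n_pairs
    w = same.T.astype(float)
    b = (~same).T.astype(float)
    null = (filled @ w) / (valid @ w) - (filled @ b) / (valid @ b)
    return SimilarityTestResult(
        observed=observed,
        null_values=null,
        p=_permutation_pvalue(observed, null),
        n_permutations=permutations.shape[0],
        within_mean_a=wa,
        within_mean_b=wb,
        between_mean=bt,
    )


def generate_group_permutations(
    n: int, n_a: int, n_permutations: int, seed: int
) -> np.ndarray:
    """Boolean (n_permutations x n) matrix of shuffled group-A memberships."""
    rng = np.random.default_rng(seed)
    perms = np.zeros((n_permutations, n), dtype=bool)
    for k in range(n_permutations):
        idx = rng.permutation(n)[:n_a]
        perms[k, idx] = True
    return perms


def similarity_permutation_test(
    partitions_a: list[Partition],
    partitions_b: list[Partition],
    n_permutations: int = 10000,
    seed: int = 0,
) -> SimilarityTestResult:
    """NMI-based permutation test of group difference in modular architecture.

    Tests whether the mean within-group pairwise NMI exceeds the mean
    between-group pairwise NMI, against a null of shuffled group membership
    (one-sided, add-one p-value).
    """
    if len(partitions_a) < 2 or len(partitions_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    pooled = list(partitions_a) + list(partitions_b)
    sim = pairwise_similarity_matrix(pooled)
    return permutation_test_from_similarity(
        sim, n_a=len(partitions_a), n_permutations=n_permutations, seed=seed
    )


def select_representative(partitions: list[Partition]) -> int:
    """Index of the partition with the highest mean NMI to all others.

    Ties resolve to the lowest index; a single partition returns index 0.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    if len(partitions) == 1:
        return 0
    sim = pairwise_similarity_matrix(partitions)
    np.fill_diagonal(sim, 0.0)
    means = sim.sum(axis=1) / (len(partitions) - 1)
    return int(np.argmax(means))


def match_labels(p: Partition, reference: Partition) -> Partition:
    """Rename p's module ids to maximize node overlap with the reference.

    Optimal one-to-one assignment on the module contingency table; modules of
    p left unmatched receive fresh ids above the reference's maximum.  The
    partition structure (co-membership) is unchanged, so NMI to the reference
    is preserved.
    """
    if p.labels.shape != reference.labels.shape:
        raise ValueError("partitions cover different node sets")
    p_ids = np.unique(p.labels)
    r_ids = np.unique(reference.labels)
    table = np.zeros((p_ids.size, r_ids.size))
    for i, pid in enumerate(p_ids):
        for j, rid in enumerate(r_ids):
            table[i, j] = np.sum((p.labels == pid) & (reference.labels == rid))
    rows, cols = linear_sum_assignment(-table)
    mapping: dict[int, int] = {
        int(p_ids[i]): int(r_ids[j]) for i, j in zip(rows, cols)
    }
    fresh = int(r_ids.max()) + 1
    for pid in p_ids:
        if int(pid) not in mapping:
            mapping[int(pid)] = fresh
            fresh += 1
    new_labels = np.array([mapping[int(l)] for l in p.labels])
    return Partition(labels=new_labels, Q=p.Q, node_ids=p.node_ids, graph_ref=p.graph_ref)


def consensus_partition(matched: list[Partition]) -> ConsensusPartition:
    """Per-node modal label and its frequency over label-matched subjects.

    Ties go to the smaller label id.  The frequency quantifies the confidence
    of each node's module assignment within the group.
    """
    if not matched:
        raise ValueError("need at least one partition")
    labels = np.stack([p.labels for p in matched])
    n_subjects, n_nodes = labels.shape
    modal = np.empty(n_nodes, dtype=int)
    freq = np.empty(n_nodes)
    for j in range(n_nodes):
        ids, counts = np.unique(labels[:, j], return_counts=True)
        best = ids[counts == counts.max()].min()  # tie -> smaller id
        modal[j] = best
        freq[j] = counts.max() / n_subjects
    return ConsensusPartition(labels=modal, frequency=freq, node_ids=matched[0].node_ids)


def group_consensus(partitions: list[Partition]) -> tuple[ConsensusPartition, int]:
    """Representative selection + label matching + consensus, in one call."""
    rep = select_representative(partitions)
    matched = [
        p if i == rep else match_labels(p, partitions[rep])
        for i, p in enumerate(partitions)
    ]
    return consensus_partition(matched), rep
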