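"""Module detection, NMI, permutation tests, label matching and consensus."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score

import oracles
from conftest import graph_from_adjacency
from rsfcnet.modules import (
    Partition,
    consensus_partition,
    count_major_modules,
    detect_partition,
    group_consensus,
    match_labels,
    nmi,
    select_representative,
    similarity_permutation_test,
)


def two_clique_graph() -> np.ndarray:
    adj = np.zeros((10, 10))
    adj[:5, :5] = 1.0
    adj[5:, 5:] = 1.0
    np.fill_diagonal(adj, 0.0)
    adj[4, 5] = adj[5, 4] = 1.0
    return adj


class TestDetectPartition:
    def test_two_cliques_recovered_with_closed_form_q(self):
        p = detect_partition(graph_from_adjacency(two_clique_graph()), seed=0, n_restarts=5)
        labels = p.labels
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[9]
        assert p.Q == pytest.approx(20 / 21 - 0.5, abs=1e-9)

    def test_complete_graph_single_module(self):
        p = detect_partition(graph_from_adjacency(np.ones((6, 6)) - np.eye(6)), seed=0)
        assert p.Q <= 0.0 + 1e-12
        assert len(p.module_sizes()) == 1

    def test_planted_four_module_recovery(self):
        rng = np.random.default_rng(0)
        planted = np.repeat([1, 2, 3, 4], 15)
        nmis = []
        for seed in range(20):
            adj = np.zeros((60, 60))
            for i in range(60):
                for j in range(i + 1, 60):
                    prob = 0.8 if planted[i] == planted[j] else 0.05
                    if rng.random() < prob:
                        adj[i, j] = adj[j, i] = 1.0
            p = detect_partition(graph_from_adjacency(adj), seed=seed, n_restarts=5)
            nmis.append(nmi(p.labels, planted))
        assert np.mean(nmis) >= 0.9

    def test_detected_q_at_least_planted_q(self):
        adj = two_clique_graph()
        g = graph_from_adjacency(adj)
        planted = [set(range(5)), set(range(5, 10))]
        planted_q = nx.community.modularity(g.to_networkx(), planted)
        p = detect_partition(g, seed=3, n_restarts=20)
        assert p.Q >= planted_q - 1e-9

    def test_weighted_modularity_used_in_weighted_mode(self):
        adj = two_clique_graph() * 0.7
        from rsfcnet.connectivity import ThresholdedGraph

        g = ThresholdedGraph(adj, cost=0.5, mode="weighted",
                             node_ids=[f"n{i}" for i in range(10)])
        p = detect_partition(g, seed=0, n_restarts=5)
        assert len(set(p.labels[:5])) == 1
        assert p.Q == pytest.approx(20 / 21 - 0.5, abs=1e-9)


class TestCountMajorModules:
    def test_threshold_at_six_nodes(self):
        labels = np.array([1] * 10 + [2] * 7 + [3] * 3)
        assert count_major_modules(Partition(labels=labels)) == 2

    def test_all_singletons(self):
        assert count_major_modules(Partition(labels=np.arange(8))) == 0


class TestNmi:
    def test_self_similarity_is_one(self):
        p = Partition(labels=np.array([1, 1, 2, 2, 3]))
        assert nmi(p, p) == pytest.approx(1.0)

    def test_independent_partitions_zero(self):
        assert nmi(np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2])) == pytest.approx(0.0)

    def test_single_module_conventions(self):
        ones = np.ones(4, dtype=int)
        assert nmi(ones, ones) == 1.0
        assert nmi(ones, np.array([1, 1, 2, 2])) == 0.0

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node set"):
            nmi(np.ones(3, dtype=int), np.ones(4, dtype=int))

    @given(st.lists(st.integers(1, 4), min_size=4, max_size=12),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_range_and_relabel_invariance(self, labels, rnd):
        a = np.asarray(labels)
        b = np.asarray([rnd.randint(1, 3) for _ in labels])
        assert nmi(a, b) == pytest.approx(nmi(b, a))
        assert 0.0 <= nmi(a, b) <= 1.0
        remap = {v: i + 10 for i, v in enumerate(set(labels))}
        assert nmi(np.asarray([remap[v] for v in labels]), b) == pytest.approx(nmi(a, b))

    def test_matches_sklearn_on_random_labelings(self, rng):
        for _ in range(100):
            a = rng.integers(1, 5, 30)
            b = rng.integers(1, 5, 30)
            expected = normalized_mutual_info_score(a, b, average_method="arithmetic")
            assert nmi(a, b) == pytest.approx(expected, abs=1e-12)

    def test_one_iff_identical_up_to_relabeling_brute_force(self):
        # exhaustive over all set partitions of 5 nodes
        blocks = list(oracles.set_partitions(list(range(5))))
        labelings = [oracles.partition_to_labels(b, 5) for b in blocks]
        for i, la in enumerate(labelings):
            for j, lb in enumerate(labelings):
                value = nmi(la, lb)
                if i == j:
                    assert value == pytest.approx(1.0)
                elif value == pytest.approx(1.0):
                    # NMI 1 must imply identical co-membership structure
                    same = np.equal.outer(la, la) == np.equal.outer(lb, lb)
                    assert same.all()


class TestSimilarityPermutationTest:
    def test_identical_subjects_give_p_one(self):
        p = Partition(labels=np.array([1, 1, 2, 2, 3, 3]))
        result = similarity_permutation_test([p, p, p], [p, p, p],
                                             n_permutations=200, seed=0)
        assert result.observed == pytest.approx(0.0)
        assert result.p == 1.0

    def test_distinct_groups_detected(self):
        pa = Partition(labels=np.repeat([1, 2, 3], 10))
        pb = Partition(labels=np.repeat([1, 2, 3], [14, 8, 8]))
        rng = np.random.default_rng(0)

        def jitter(p):
            labels = p.labels.copy()
            idx = rng.integers(0, 30, 2)
            labels[idx] = rng.integers(1, 4, 2)
            return Partition(labels=labels)

        group_a = [jitter(pa) for _ in range(8)]
        group_b = [jitter(pb) for _ in range(8)]
        result = similarity_permutation_test(group_a, group_b,
                                             n_permutations=500, seed=1)
        assert result.p < 0.05
        assert result.observed > 0

    def test_pvalue_never_zero_and_add_one_rule(self):
        pa = Partition(labels=np.repeat([1, 2], 10))
        pb = Partition(labels=np.repeat([1, 2], [15, 5]))
        result = similarity_permutation_test([pa] * 5, [pb] * 5,
                                             n_permutations=300, seed=2)
        assert 0 < result.p <= 1.0
        expected = (1 + np.sum(result.null_values >= result.observed)) / (1 + 300)
        assert result.p == pytest.approx(expected)

    def test_too_few_subjects_rejected(self):
        p = Partition(labels=np.array([1, 2, 1, 2]))
        with pytest.raises(ValueError, match="at least 2"):
            similarity_permutation_test([p], [p, p], n_permutations=10, seed=0)


class TestRepresentativeAndMatching:
    def test_majority_representative_lowest_index(self):
        common = Partition(labels=np.repeat([1, 2], 5))
        odd = Partition(labels=np.array([1, 2] * 5))
        parts = [common] * 4 + [odd] + [common] * 5
        assert select_representative(parts) == 0

    def test_single_partition_returns_zero(self):
        assert select_representative([Partition(labels=np.array([1, 1, 2]))]) == 0

    def test_highest_mean_similarity_wins(self):
        a = Partition(labels=np.array([1, 1, 2, 2, 3, 3]))
        b = Partition(labels=np.array([1, 1, 2, 2, 2, 3]))  # between a and c
        c = Partition(labels=np.array([1, 2, 2, 2, 2, 3]))
        assert select_representative([a, b, c]) == 1

    def test_permuted_ids_matched_back(self):
        ref = Partition(labels=np.array([1, 1, 2, 2, 3, 3]))
        permuted = Partition(labels=np.array([3, 3, 1, 1, 2, 2]))
        matched = match_labels(permuted, ref)
        np.testing.assert_array_equal(matched.labels, ref.labels)

    def test_matching_preserves_structure_and_nmi(self):
        rng = np.random.default_rng(1)
        p = Partition(labels=rng.integers(1, 5, 30))
        ref = Partition(labels=rng.integers(1, 4, 30))
        matched = match_labels(p, ref)
        assert np.array_equal(
            np.equal.outer(p.labels, p.labels),
            np.equal.outer(matched.labels, matched.labels),
        )
        assert nmi(matched, ref) == pytest.approx(nmi(p, ref))

    def test_extra_module_gets_one_fresh_id(self):
        p = Partition(labels=np.array([1, 1, 2, 2, 3, 3]))
        ref = Partition(labels=np.array([1, 1, 1, 2, 2, 2]))
        matched = match_labels(p, ref)
        fresh = set(matched.labels) - set(ref.labels)
        assert len(fresh) == 1
        assert min(fresh) > max(ref.labels)


class TestConsensus:
    def test_identical_subjects_full_confidence(self):
        p = Partition(labels=np.array([1, 1, 2, 2]))
        consensus = consensus_partition([p, p, p])
        np.testing.assert_array_equal(consensus.labels, p.labels)
        assert np.all(consensus.frequency == 1.0)

    def test_modal_label_and_frequency(self):
        base = np.array([1, 1, 2, 2])
        variant = np.array([2, 1, 2, 2])
        parts = [Partition(labels=base)] * 7 + [Partition(labels=variant)] * 3
        consensus = consensus_partition(parts)
        assert consensus.labels[0] == 1
        assert consensus.frequency[0] == pytest.approx(0.7)

    def test_tie_goes_to_smaller_label(self):
        parts = [Partition(labels=np.array([1, 3])), Partition(labels=np.array([2, 3]))]
        consensus = consensus_partition(parts)
        assert consensus.labels[0] == 1

    def test_group_consensus_pipeline(self):
        rng = np.random.default_rng(0)
        base = np.repeat([1, 2, 3], 8)
        parts = []
        for _ in range(9):
            labels = base.copy()
            flip = rng.integers(0, 24, 2)
            labels[flip] = rng.integers(1, 4, 2)
            # random relabeling to exercise matching
            perm = rng.permutation([1, 2, 3])
            parts.append(Partition(labels=perm[labels - 1]))
        consensus, rep = group_consensus(parts)
        assert 0 <= rep < 9
        assert nmi(consensus.labels, base) > 0.8
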