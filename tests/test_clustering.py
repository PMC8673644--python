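"""Graph clustering primitives against independent brute-force oracles."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from clickchain import clustering
from clickchain.clustering import (
    Partition,
    SimilarityGraph,
    UNCLUSTERED,
    chinese_whispers,
    correlation_similarity,
    merge_near_duplicates,
    normalized_mutual_information,
    prune_edges,
    prune_weak_nodes,
    select_best_partition,
    subsample_nodes,
)


def brute_force_pearson_clipped(X):
    """Textbook covariance/σ computation, clipped to [0, 1], zero diagonal."""
    n = len(X)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
            denom = np.sqrt((xi**2).sum() * (xj**2).sum())
            r = (xi * xj).sum() / denom if denom > 0 else 0.0
            W[i, j] = min(max(r, 0.0), 1.0)
    return W


def planted_block_graph(n_per_block=30, n_blocks=3, within=0.9, between=0.05):
    n = n_per_block * n_blocks
    labels = np.repeat(np.arange(n_blocks), n_per_block)
    W = np.where(labels[:, None] == labels[None, :], within, between)
    np.fill_diagonal(W, 0.0)
    return SimilarityGraph(W), labels


class TestCorrelationSimilarity:
    def test_identical_rows_have_weight_one(self):
        X = np.tile(np.arange(10.0), (3, 1))
        g = correlation_similarity(X)
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_negation_clips_to_zero(self):
        x = np.arange(10.0)
        g = correlation_similarity(np.vstack([x, -x]))
        assert g.weights[0, 1] == 0.0

    def test_matches_textbook_pearson(self, rng):
        X = rng.normal(size=(12, 10))
        g = correlation_similarity(X)
        np.testing.assert_allclose(g.weights, brute_force_pearson_clipped(X), atol=1e-10)

    def test_zero_variance_row_warns_and_isolates(self, rng):
        X = rng.normal(size=(4, 8))
        X[2] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            g = correlation_similarity(X)
        assert np.all(g.weights[2] == 0) and np.all(g.weights[:, 2] == 0)


class TestPruneEdges:
    def test_retain_all_is_identity(self, rng):
        g = correlation_similarity(rng.normal(size=(8, 6)))
        pruned = prune_edges(g, 1.0)
        np.testing.assert_allclose(np.asarray(pruned.weights), g.weights)

    def test_matches_sort_oracle(self, rng):
        g = correlation_similarity(rng.normal(size=(15, 10)))
        pruned = prune_edges(g, 0.10)
        kept = sorted(w for _, _, w in pruned.edge_list())
        all_w = np.sort(g.weights[np.triu_indices(15, 1)])
        n_expected = int(np.ceil(0.10 * len(all_w)))
        cutoff = all_w[-n_expected]
        dropped_max = all_w[all_w < cutoff].max()
        assert min(kept) >= cutoff > dropped_max

    def test_ties_at_cutoff_all_kept(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 0.9
        W[1, 2] = W[2, 1] = 0.5
        W[2, 3] = W[3, 2] = 0.5
        W[3, 4] = W[4, 3] = 0.2
        pruned = prune_edges(SimilarityGraph(W), 0.2)  # 2 of 10 pairs
        weights = [w for _, _, w in pruned.edge_list()]
        assert sorted(weights) == [0.5, 0.5, 0.9]

    def test_edge_set_monotone_in_fraction(self, rng):
        g = correlation_similarity(rng.normal(size=(12, 8)))
        small = {(i, j) for i, j, _ in prune_edges(g, 0.05).edge_list()}
        large = {(i, j) for i, j, _ in prune_edges(g, 0.30).edge_list()}
        assert small <= large


class TestMergeNearDuplicates:
    def test_identical_rows_collapse_with_count(self):
        X = np.vstack([np.arange(8.0)] * 3 + [np.arange(8.0)[::-1]])
        g = correlation_similarity(X)
        reduced, members = merge_near_duplicates(g, 0.99)
        assert reduced.n_nodes == 2
        sizes = sorted(len(v) for v in members.values())
        assert sizes == [1, 3]

    def test_no_pairs_above_threshold_is_identity(self, rng):
        g = correlation_similarity(rng.normal(size=(6, 20)))
        reduced, members = merge_near_duplicates(g, 0.999)
        assert reduced.n_nodes == 6
        assert all(len(v) == 1 for v in members.values())

    def test_transitive_closure_matches_connected_components(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.99
        W[1, 2] = W[2, 1] = 0.99
        W[0, 2] = W[2, 0] = 0.5
        reduced, members = merge_near_duplicates(SimilarityGraph(W), 0.98)
        assert reduced.n_nodes == 1
        assert len(members[0]) == 3


class TestSubsample:
    def test_small_pool_unchanged(self):
        ids = np.arange(5000)
        np.testing.assert_array_equal(subsample_nodes(ids, 10_000, 0), ids)

    def test_seeded_reproducibility(self):
        ids = np.arange(20_000)
        a = subsample_nodes(ids, 10_000, 42)
        b = subsample_nodes(ids, 10_000, 42)
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self):
        ids = np.arange(20_000)
        a = set(subsample_nodes(ids, 10_000, 1).tolist())
        b = set(subsample_nodes(ids, 10_000, 2).tolist())
        # hypergeometric overlap ~5000 ± ~50; identical sets are impossible in practice
        assert len(a & b) < 6000


class TestChineseWhispers:
    def test_disconnected_cliques_recovered_exactly(self):
        W = np.zeros((10, 10))
        W[:5, :5] = 0.8
        W[5:, 5:] = 0.8
        np.fill_diagonal(W, 0.0)
        part = chinese_whispers(SimilarityGraph(W), seed=0)
        assert part.n_clusters == 2
        assert len(set(part.labels[:5])) == 1 and len(set(part.labels[5:])) == 1

    def test_single_node_is_singleton(self):
        part = chinese_whispers(SimilarityGraph(np.zeros((1, 1))), seed=0)
        assert part.n_clusters == 1

    def test_empty_graph(self):
        part = chinese_whispers(SimilarityGraph(np.zeros((0, 0))), seed=0)
        assert len(part.labels) == 0

    def test_planted_blocks_recovered(self):
        g, truth = planted_block_graph()
        hits = 0
        for seed in range(5):
            part = chinese_whispers(g, seed=seed)
            if adjusted_rand_score(truth, part.labels) >= 0.95:
                hits += 1
        assert hits >= 4

    def test_label_count_never_exceeds_node_count(self, rng):
        g = correlation_similarity(rng.normal(size=(20, 10)))
        part = chinese_whispers(prune_edges(g, 0.3), seed=3)
        assert part.n_clusters <= 20


def brute_force_nmi(lp, lq):
    """Contingency-table entropy computation, arithmetic normalization."""
    lp, lq = np.asarray(lp), np.asarray(lq)
    n = len(lp)
    cp = {a: (lp == a).sum() / n for a in set(lp.tolist())}
    cq = {b: (lq == b).sum() / n for b in set(lq.tolist())}
    hp = -sum(p * np.log(p) for p in cp.values())
    hq = -sum(p * np.log(p) for p in cq.values())
    mi = 0.0
    for a in cp:
        for b in cq:
            pab = ((lp == a) & (lq == b)).sum() / n
            if pab > 0:
                mi += pab * np.log(pab / (cp[a] * cq[b]))
    if hp == 0 and hq == 0:
        return 1.0
    if hp == 0 or hq == 0:
        return 0.0
    return 2 * mi / (hp + hq)


class TestNMI:
    def test_identical_partitions(self):
        p = Partition(np.array([0, 0, 1, 1, 2]))
        assert normalized_mutual_information(p, p) == pytest.approx(1.0)

    def test_single_cluster_vs_halves_is_zero(self):
        p = Partition(np.zeros(6, dtype=int))
        q = Partition(np.array([0, 0, 0, 1, 1, 1]))
        assert normalized_mutual_information(p, q) == 0.0

    def test_matches_contingency_oracle(self):
        lp = np.array([0, 0, 1, 1, 2, 2])
        lq = np.array([0, 1, 1, 1, 2, 0])
        got = normalized_mutual_information(Partition(lp), Partition(lq))
        assert got == pytest.approx(brute_force_nmi(lp, lq), abs=1e-10)

    def test_symmetric_and_label_invariant(self, rng):
        lp = rng.integers(0, 3, 30)
        lq = rng.integers(0, 4, 30)
        a = normalized_mutual_information(Partition(lp), Partition(lq))
        b = normalized_mutual_information(Partition(lq), Partition(lp))
        c = normalized_mutual_information(Partition(lp + 7), Partition(lq))
        assert a == pytest.approx(b) == pytest.approx(c)
        assert 0.0 <= a <= 1.0


class TestSelectBestPartition:
    def test_identical_candidates_returned(self):
        p = Partition(np.array([0, 0, 1, 1]))
        assert select_best_partition([p] * 5) is p

    def test_outlier_rejected(self):
        same = [Partition(np.array([0, 0, 1, 1, 2, 2])) for _ in range(4)]
        outlier = Partition(np.array([0, 1, 2, 3, 4, 5]))
        best = select_best_partition(same + [outlier])
        assert any(best is s for s in same)

    def test_single_candidate_passthrough(self):
        p = Partition(np.array([0, 1]))
        assert select_best_partition([p]) is p


class TestPruneWeakNodes:
    def test_zero_fraction_is_identity(self, rng):
        g = correlation_similarity(rng.normal(size=(10, 8)))
        part = chinese_whispers(g, seed=0)
        out = prune_weak_nodes(g, part, 0.0)
        np.testing.assert_array_equal(out.labels, part.labels)

    def test_weakest_member_removed_matches_strength_sort(self):
        W = np.full((10, 10), 0.9)
        np.fill_diagonal(W, 0.0)
        W[9, :] = W[:, 9] = 0.1  # node 9 weakly connected
        np.fill_diagonal(W, 0.0)
        g = SimilarityGraph(W)
        part = Partition(np.zeros(10, dtype=int))
        out = prune_weak_nodes(g, part, 0.1)
        assert out.labels[9] == UNCLUSTERED
        assert (out.labels[:9] == 0).all()

    def test_singleton_cluster_survives(self):
        g = SimilarityGraph(np.zeros((1, 1)))
        out = prune_weak_nodes(g, Partition(np.array([0])), 0.1)
        assert out.labels[0] == 0
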