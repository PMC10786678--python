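"""Spectral quasi-rigid clustering: kernel, embedding, scoring, selection."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from shellmech.elastic_models import build_network, uenm_hessian
from shellmech.fixtures import make_hinged_toy, planted_gammas
from shellmech.fluctuations import PairFluctuations, distance_fluctuation_matrix, pair_list
from shellmech.modes import compute_modes
from shellmech.qrc import (
    SimilarityGraph,
    cluster_embedding,
    fluctuation_contrast,
    quality_score,
    scan_clusters,
    similarity_graph,
    spectral_embedding,
)


def _fluct(sigma2, pairs=None, n_nodes=None):
    sigma2 = np.asarray(sigma2, float)
    if pairs is None:
        pairs = np.array([[0, k + 1] for k in range(len(sigma2))])
    n = n_nodes or int(pairs.max()) + 1
    return PairFluctuations(np.asarray(pairs), sigma2, 10.0, n)


def toy_graph(dom=3, size=25, stiffness_ratio=100.0, seed=1, n_modes=100):
    toy = make_hinged_toy(dom, size, stiffness_ratio=stiffness_ratio, seed=seed)
    net = build_network(toy.structure, "uenm", cutoff=7.5)
    planted_gammas(net, toy)
    h = uenm_hessian(net, 0.5)
    modes = compute_modes(h, min(n_modes, h.dim - h.n_rigid_expected - 1))
    pairs = pair_list(toy.structure, 15.0)
    fl = distance_fluctuation_matrix(modes, toy.structure, pairs, 15.0)
    return toy, similarity_graph(fl)


def two_cliques_graph(m=6, weak=0.01):
    pairs, weights = [], []
    for a in range(2 * m):
        for b in range(a + 1, 2 * m):
            if (a < m) == (b < m):
                pairs.append((a, b)); weights.append(1.0)
    pairs.append((m - 1, m)); weights.append(weak)
    return SimilarityGraph(np.array(pairs), np.array(weights), 2 * m)


class TestSimilarityKernel:
    def test_formula_on_fixture_table(self):
        sigma2 = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        g = similarity_graph(_fluct(sigma2))
        np.testing.assert_allclose(
            g.weights, np.exp(-sigma2 / (2.0 * sigma2.mean())))

    def test_mean_sigma_maps_to_exp_minus_half(self):
        g = similarity_graph(_fluct([3.0, 3.0, 3.0]))
        np.testing.assert_allclose(g.weights, np.exp(-0.5))

    def test_zero_sigma_gives_unit_weight(self):
        g = similarity_graph(_fluct([0.0, 2.0]))
        assert g.weights[0] == 1.0

    def test_perfectly_rigid_input_rejected(self):
        with pytest.raises(ValueError, match="rigid"):
            similarity_graph(_fluct([0.0, 0.0, 0.0]))


class TestSpectralEmbedding:
    def test_two_cliques_separate(self):
        g = two_cliques_graph()
        emb = spectral_embedding(g, 2)
        a, b = emb[:6], emb[6:]
        spread = max(np.linalg.norm(a - a.mean(0), axis=1).max(),
                     np.linalg.norm(b - b.mean(0), axis=1).max())
        gap = np.linalg.norm(a.mean(0) - b.mean(0))
        assert gap > 10 * spread
        for method in ("discretize", "kmeans"):
            labels = cluster_embedding(emb, 2, method=method, seed=0)
            assert adjusted_rand_score([0] * 6 + [1] * 6, labels) == 1.0

    def test_uniform_complete_graph_orthogonality(self):
        n = 8
        pairs = np.array([(a, b) for a in range(n) for b in range(a + 1, n)])
        g = SimilarityGraph(pairs, np.ones(len(pairs)), n)
        from shellmech.qrc import _embedding_vectors

        vecs = _embedding_vectors(g, 2)
        assert abs(vecs[:, 1].sum()) < 1e-8

    def test_matches_dense_laplacian_oracle(self):
        # force the sparse eigensolver path with a larger random graph
        rng = np.random.default_rng(4)
        n = 80
        pairs = np.array([(a, a + 1) for a in range(n - 1)] +
                         [tuple(sorted(p)) for p in
                          {tuple(rng.integers(0, n, 2)) for _ in range(300)}
                          if p[0] != p[1]])
        pairs = np.unique(np.sort(pairs, axis=1), axis=0)
        weights = rng.uniform(0.1, 1.0, len(pairs))
        g = SimilarityGraph(pairs, weights, n)
        from shellmech.qrc import _embedding_vectors

        vecs = _embedding_vectors(g, 5)
        s = g.adjacency().toarray()
        d = s.sum(1)
        lap = np.eye(n) - s / np.sqrt(np.outer(d, d))
        w, v = np.linalg.eigh(lap)
        for k in range(5):
            assert abs(v[:, k] @ vecs[:, k]) == pytest.approx(1.0, abs=1e-8)


class TestClusterEmbedding:
    def test_every_point_its_own_cluster(self):
        x = np.arange(10, dtype=float).reshape(-1, 1) * 5.0
        labels = cluster_embedding(x, 10, method="kmeans", seed=0)
        assert len(np.unique(labels)) == 10

    def test_duplicate_rows_co_clustered(self):
        x = np.array([[0.0, 0], [0, 0], [10, 0], [10, 0], [0, 10], [0, 10]])
        for method in ("kmeans",):
            labels = cluster_embedding(x, 3, method=method, seed=0)
            assert labels[0] == labels[1]
            assert labels[2] == labels[3]
            assert labels[4] == labels[5]

    def test_too_few_distinct_rows(self):
        x = np.zeros((5, 2))
        with pytest.raises(ValueError):
            cluster_embedding(x, 2)


class TestQualityScore:
    def test_hand_computed_square(self):
        x = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        labels = np.array([0, 1, 0, 1])
        # own-centroid distance 0.5, other centroid sqrt(1.25)
        assert quality_score(x, labels) == pytest.approx(np.sqrt(1.25) / 0.5)

    def test_all_points_coincident_scores_one(self):
        x = np.zeros((6, 3))
        assert quality_score(x, np.array([0, 0, 0, 1, 1, 1])) == 1.0

    def test_swapping_labels_across_groups_decreases_score(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.05, (10, 2))
        b = rng.normal(5, 0.05, (10, 2)) + [5.0, 0.0]
        x = np.vstack([a, b])
        labels = np.array([0] * 10 + [1] * 10)
        swapped = labels.copy()
        swapped[[0, 10]] = swapped[[10, 0]]
        assert quality_score(x, swapped) < quality_score(x, labels)

    def test_score_grows_with_separation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, (8, 2))
        b = rng.normal(0, 0.1, (8, 2))
        labels = np.array([0] * 8 + [1] * 8)
        near = quality_score(np.vstack([a, b + [3.0, 0]]), labels)
        far = quality_score(np.vstack([a, b + [30.0, 0]]), labels)
        assert far > near

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, 30)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, 30)
        perm = np.array([2, 0, 1])
        assert quality_score(x, labels) == pytest.approx(
            quality_score(x, perm[labels]))


class TestFluctuationContrast:
    def test_permutation_and_scale_invariance(self):
        toy, g = toy_graph(seed=2)
        labels = toy.true_labels
        q = fluctuation_contrast(g, labels)
        perm = np.array([1, 2, 0])
        assert fluctuation_contrast(g, perm[labels]) == pytest.approx(q)
        # rescaling sigma2 only enters through the mean-normalized kernel
        g2 = SimilarityGraph(g.pairs, g.weights**1.0, g.n_nodes)
        assert fluctuation_contrast(g2, labels) == pytest.approx(q)

    def test_sigma_rescaling_leaves_labels_unchanged(self):
        toy = make_hinged_toy(3, 20, stiffness_ratio=100.0, seed=4)
        net = build_network(toy.structure, "uenm", cutoff=7.5)
        planted_gammas(net, toy)
        h = uenm_hessian(net, 0.5)
        modes = compute_modes(h, 60)
        pairs = pair_list(toy.structure, 15.0)
        fl = distance_fluctuation_matrix(modes, toy.structure, pairs, 15.0)
        scaled = PairFluctuations(fl.pairs, 7.3 * fl.sigma2, 15.0, fl.n_nodes)
        r1 = scan_clusters(similarity_graph(fl), 2, 6, seed=0)
        r2 = scan_clusters(similarity_graph(scaled), 2, 6, seed=0)
        for k in r1.labels_by_k:
            np.testing.assert_array_equal(r1.labels_by_k[k], r2.labels_by_k[k])

    def test_planted_partition_beats_merges_and_splits(self):
        toy, g = toy_graph(seed=3)
        q_true = fluctuation_contrast(g, toy.true_labels)
        merged = np.minimum(toy.true_labels, 1)  # swallow one interface
        assert fluctuation_contrast(g, merged) < q_true


class TestScanClusters:
    @pytest.mark.parametrize("method", ["discretize", "kmeans"])
    def test_planted_recovery_and_maximum_at_planted_k(self, method):
        for seed in (0, 1, 2):
            toy, g = toy_graph(dom=3, size=25, seed=seed)
            res = scan_clusters(g, 2, 6, method=method, seed=0)
            assert res.selected_k == 3
            ari = adjusted_rand_score(toy.true_labels, res.selected_labels)
            assert ari >= 0.99

    def test_single_k_scan(self):
        _, g = toy_graph(seed=1)
        res = scan_clusters(g, 5, 5, seed=0)
        assert res.k_values.tolist() == [5]
        assert res.selected_k == 5
        assert len(res.labels_by_k[5]) == g.n_nodes

    def test_deterministic_to_the_bit(self):
        _, g = toy_graph(seed=2)
        r1 = scan_clusters(g, 2, 6, seed=0)
        r2 = scan_clusters(g, 2, 6, seed=0)
        np.testing.assert_array_equal(r1.quality_by_k, r2.quality_by_k)
        for k in r1.labels_by_k:
            np.testing.assert_array_equal(r1.labels_by_k[k], r2.labels_by_k[k])

    def test_two_scale_structure_reports_both_maxima(self):
        # six domains on a ring in two super-groups of three: soft springs
        # inside a super-group, ultra-soft across super-groups
        toy = make_hinged_toy(6, 15, seed=4)
        net = build_network(toy.structure, "uenm", cutoff=7.5)
        lab = toy.true_labels
        sup = lab // 3
        i, j = net.edges[:, 0], net.edges[:, 1]
        net.gammas = np.where(lab[i] == lab[j], 1.0,
                              np.where(sup[i] == sup[j], 0.05, 1e-4))
        h = uenm_hessian(net, 0.5)
        modes = compute_modes(h, min(100, h.dim - h.n_rigid_expected - 1))
        pairs = pair_list(toy.structure, 15.0)
        fl = distance_fluctuation_matrix(modes, toy.structure, pairs, 15.0)
        res = scan_clusters(similarity_graph(fl), 2, 8, seed=0)
        assert len(res.local_maxima) >= 2
        assert 2 in res.local_maxima and 6 in res.local_maxima
        ari_coarse = adjusted_rand_score(sup, res.labels_by_k[2])
        assert ari_coarse >= 0.99
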