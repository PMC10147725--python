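import networkx as nx
import numpy as np
import pytest

from conftest import graph_from_weights
from oracles import (
    floyd_warshall_oracle,
    modularity_oracle,
    onnela_clustering_oracle,
    random_weighted_matrix,
)
from wmnet import (
    ValidationError,
    WeightedGraph,
    characteristic_path_length,
    clustering_coefficient,
    compute_all,
    hubness_score,
    modularity_louvain,
    modularity_q,
    nodal_efficiency,
    shortest_path_lengths,
    small_worldness,
)


def weights_of(edges, n):
    w = np.zeros((n, n))
    for a, b, v in edges:
        w[a, b] = w[b, a] = v
    return w


class TestClustering:
    def test_unit_triangle_is_fully_clustered(self):
        g = graph_from_weights(weights_of([(0, 1, 1), (1, 2, 1), (0, 2, 1)], 3))
        per_node, mean = clustering_coefficient(g)
        np.testing.assert_allclose(per_node, 1.0)
        assert mean == 1.0

    def test_path_has_no_triangles(self):
        g = graph_from_weights(weights_of([(0, 1, 1), (1, 2, 1)], 3))
        per_node, mean = clustering_coefficient(g)
        np.testing.assert_allclose(per_node, 0.0)
        assert mean == 0.0

    def test_geometric_mean_weighted_triangle(self):
        # C_A = (1 * 1 * 0.125)^(1/3) = 0.5 with max-weight normalization
        g = graph_from_weights(
            weights_of([(0, 1, 1.0), (0, 2, 1.0), (1, 2, 0.125)], 3)
        )
        per_node, _ = clustering_coefficient(g)
        assert per_node[0] == pytest.approx(0.5)

    def test_matches_exhaustive_triple_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            w = random_weighted_matrix(rng, 9)
            g = graph_from_weights(w)
            per_node, _ = clustering_coefficient(g)
            np.testing.assert_allclose(
                per_node, onnela_clustering_oracle(w), atol=1e-12
            )

    def test_empty_graph_rejected(self):
        g = WeightedGraph(nx.Graph(), 0.0, [])
        with pytest.raises(ValidationError):
            clustering_coefficient(g)


class TestDistances:
    def test_single_edge_inverse_weight(self):
        g = graph_from_weights(weights_of([(0, 1, 0.5)], 3))
        d = shortest_path_lengths(g)
        assert d[0, 1] == pytest.approx(2.0)
        assert np.isinf(d[0, 2])

    def test_unit_path_distances(self):
        g = graph_from_weights(weights_of([(0, 1, 1), (1, 2, 1)], 3))
        assert shortest_path_lengths(g)[0, 2] == pytest.approx(2.0)

    def test_matches_floyd_warshall(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = random_weighted_matrix(rng, 8)
            g = graph_from_weights(w)
            np.testing.assert_allclose(
                shortest_path_lengths(g), floyd_warshall_oracle(w), rtol=1e-10
            )


class TestCharacteristicPathLength:
    def test_complete_unit_graph(self):
        w = 1.0 - np.eye(4)
        lp, excl = characteristic_path_length(graph_from_weights(w))
        assert lp == pytest.approx(1.0)
        assert excl == 0

    def test_three_node_unit_path(self):
        g = graph_from_weights(weights_of([(0, 1, 1), (1, 2, 1)], 3))
        lp, _ = characteristic_path_length(g)
        assert lp == pytest.approx(4.0 / 3.0)

    def test_isolated_node_excluded_not_contaminating(self):
        g3 = graph_from_weights(weights_of([(0, 1, 1), (1, 2, 1)], 3))
        g4 = graph_from_weights(weights_of([(0, 1, 1), (1, 2, 1)], 4))
        lp3, _ = characteristic_path_length(g3)
        lp4, excl = characteristic_path_length(g4)
        assert lp4 == pytest.approx(lp3)
        assert excl == 6  # ordered pairs involving the isolated node

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValidationError):
            characteristic_path_length(graph_from_weights(np.zeros((3, 3))))


class TestNodalEfficiency:
    def test_star_center_perfect(self, unit_star):
        enod = nodal_efficiency(unit_star)
        assert enod[0] == pytest.approx(1.0)

    def test_star_leaf_two_thirds(self, unit_star):
        enod = nodal_efficiency(unit_star)
        np.testing.assert_allclose(enod[1:], 2.0 / 3.0)

    def test_isolated_node_zero(self):
        g = graph_from_weights(weights_of([(0, 1, 1)], 3))
        assert nodal_efficiency(g)[2] == 0.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        w = random_weighted_matrix(rng, 7)
        perm = rng.permutation(7)
        e1 = nodal_efficiency(graph_from_weights(w))
        e2 = nodal_efficiency(graph_from_weights(w[np.ix_(perm, perm)]))
        np.testing.assert_allclose(e1[perm], e2, rtol=1e-10)

    def test_weight_scaling_never_decreases(self):
        rng = np.random.default_rng(9)
        w = random_weighted_matrix(rng, 7) * 0.4
        e1 = nodal_efficiency(graph_from_weights(w))
        e2 = nodal_efficiency(graph_from_weights(np.clip(2.0 * w, 0, 1)))
        assert (e2 >= e1 - 1e-12).all()


class TestModularity:
    def test_single_clique_single_community_zero(self):
        w = 1.0 - np.eye(5)
        g = graph_from_weights(w)
        assert modularity_q(g, [set(range(5))]) == pytest.approx(0.0)

    def test_two_triangles_attain_half(self, two_triangles):
        assert modularity_q(
            two_triangles, [{0, 1, 2}, {3, 4, 5}]
        ) == pytest.approx(0.5)
        _, q = modularity_louvain(two_triangles, seed=0, restarts=5)
        assert q == pytest.approx(0.5)

    def test_two_triangles_half_is_optimal_by_exhaustion(self, two_triangles):
        # all partitions of 6 nodes, generated by restricted growth strings
        def partitions(n):
            def rec(prefix, m):
                if len(prefix) == n:
                    yield prefix
                    return
                for c in range(m + 2):
                    yield from rec(prefix + [c], max(m, c))

            yield from rec([0], 0)

        best = -1.0
        for labels in partitions(6):
            comms = {}
            for node, c in enumerate(labels):
                comms.setdefault(c, set()).add(node)
            best = max(best, modularity_q(two_triangles, list(comms.values())))
        assert best == pytest.approx(0.5)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(15):
            w = random_weighted_matrix(rng, 8)
            if not w.any():
                continue
            g = graph_from_weights(w)
            labels = rng.integers(0, 3, size=8)
            comms = [set(np.nonzero(labels == c)[0]) for c in range(3)]
            comms = [c for c in comms if c]
            assert modularity_q(g, comms) == pytest.approx(
                modularity_oracle(w, comms), abs=1e-12
            )

    def test_louvain_beats_trivial_partitions(self):
        rng = np.random.default_rng(8)
        w = random_weighted_matrix(rng, 10)
        g = graph_from_weights(w)
        _, q = modularity_louvain(g, seed=0, restarts=5)
        singletons = [{i} for i in range(10)]
        rand_labels = rng.integers(0, 3, size=10)
        rand = [set(np.nonzero(rand_labels == c)[0]) for c in range(3)]
        assert q >= modularity_q(g, singletons) - 1e-12
        assert q >= modularity_q(g, [c for c in rand if c]) - 1e-12

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValidationError):
            modularity_louvain(graph_from_weights(np.zeros((4, 4))), 0)


def ring_lattice(n=60, k=6, rewire=0.05, seed=0):
    g = nx.watts_strogatz_graph(n, k, rewire, seed=seed)
    w = np.zeros((n, n))
    for a, b in g.edges():
        w[a, b] = w[b, a] = 1.0
    return graph_from_weights(w)


class TestSmallWorldness:
    def test_lattice_is_small_world_with_cluster_check(self):
        sigma, ok, summary = small_worldness(ring_lattice(), n_null=30, seed=1)
        assert sigma > 1.0
        assert ok
        assert summary["c_rand_mean"] > 0

    def test_random_graph_sigma_near_one(self):
        g = nx.gnm_random_graph(60, 240, seed=3)
        w = np.zeros((60, 60))
        for a, b in g.edges():
            w[a, b] = w[b, a] = 1.0
        sigma, _, _ = small_worldness(graph_from_weights(w), n_null=30, seed=2)
        assert sigma == pytest.approx(1.0, abs=0.2)

    def test_zero_nulls_rejected(self, two_triangles):
        with pytest.raises(ValidationError):
            small_worldness(ring_lattice(), n_null=0)

    def test_fragmented_graph_rejected(self, two_triangles):
        with pytest.raises(ValidationError, match="90%"):
            small_worldness(two_triangles, n_null=5)


class TestHubness:
    def test_star_center_meets_all_four_criteria(self):
        n = 10
        w = np.zeros((n, n))
        for leaf in range(1, n):
            w[0, leaf] = w[leaf, 0] = 1.0
        scores = hubness_score(graph_from_weights(w))
        assert scores[0] == 4
        assert (scores[1:] <= 1).all()

    def test_symmetric_ring_all_nodes_equal(self):
        n = 8
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
        scores = hubness_score(graph_from_weights(w))
        assert len(set(scores.tolist())) == 1

    def test_too_few_nodes_rejected(self, unit_star):
        with pytest.raises(ValidationError):
            hubness_score(unit_star)


class TestComputeAll:
    def test_deterministic_given_seed(self, two_triangles):
        w = np.zeros((12, 12))
        rng = np.random.default_rng(0)
        w[:6, :6] = random_weighted_matrix(rng, 6)
        w[6:, 6:] = random_weighted_matrix(rng, 6)
        w[0, 6] = w[6, 0] = 0.5  # bridge keeps the graph connected
        g = graph_from_weights(w)
        a = compute_all(g, seed=3, n_null=10, restarts=3)
        b = compute_all(g, seed=3, n_null=10, restarts=3)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1].hubness, b[1].hubness)
        np.testing.assert_allclose(a[1].enod, b[1].enod)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            compute_all(graph_from_weights(np.zeros((5, 5))), 0, 5)

    def test_null_ensemble_sigma_centred_on_one(self):
        # a member of the null family should not look small-world vs itself
        from wmnet.metrics import _rewired_null

        base = ring_lattice(60, 6, rewire=0.05, seed=5)
        rng = np.random.default_rng(0)
        sigmas = []
        for s in range(4):
            member = _rewired_null(base, rng)
            sigmas.append(small_worldness(member, n_null=20, seed=s)[0])
        assert np.mean(sigmas) == pytest.approx(1.0, abs=0.2)
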