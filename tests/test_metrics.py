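"""Graph metrics vs hand calculations and brute-force oracles; null models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcnet import metrics as gm
from fcnet.datatypes import ConnectivityMatrix

import oracles


def adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


PATH3 = adj_from_edges(3, [(0, 1), (1, 2)])
K4 = adj_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
K5 = adj_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
STAR5 = adj_from_edges(5, [(0, i) for i in range(1, 5)])
STAR4 = adj_from_edges(4, [(0, i) for i in range(1, 4)])
CHORDED4 = adj_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
RING4 = adj_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a | a.T


class TestDistances:
    def test_complete_graph_all_distance_one(self):
        d = gm.all_pairs_shortest_paths(K5)
        off = d[~np.eye(5, dtype=bool)]
        assert np.all(off == 1)

    def test_path_graph_distance_two(self):
        d = gm.all_pairs_shortest_paths(PATH3)
        assert d[0, 2] == 2

    def test_unreachable_is_infinite(self):
        a = adj_from_edges(4, [(0, 1)])
        d = gm.all_pairs_shortest_paths(a)
        assert np.isinf(d[0, 2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall_oracle(self, seed):
        a = random_graph(12, 0.3, seed)
        np.testing.assert_array_equal(
            gm.all_pairs_shortest_paths(a), oracles.fw_distances(a)
        )


class TestHandComputedValues:
    def test_clustering_k4_is_one(self):
        _, cp = gm.clustering(K4)
        assert cp == pytest.approx(1.0)

    def test_clustering_path_is_zero(self):
        _, cp = gm.clustering(PATH3)
        assert cp == 0.0

    def test_clustering_chorded_cycle(self):
        c, cp = gm.clustering(CHORDED4)
        np.testing.assert_allclose(c, [2 / 3, 1.0, 2 / 3, 1.0])
        assert cp == pytest.approx(5 / 6)

    def test_path_length_values(self):
        assert gm.path_length(gm.all_pairs_shortest_paths(K5))[0] == 1.0
        assert gm.path_length(
            gm.all_pairs_shortest_paths(PATH3))[0] == pytest.approx(4 / 3)
        assert gm.path_length(
            gm.all_pairs_shortest_paths(RING4))[0] == pytest.approx(4 / 3)

    def test_global_efficiency_values(self):
        assert gm.global_efficiency(
            gm.all_pairs_shortest_paths(K4)) == pytest.approx(1.0)
        assert gm.global_efficiency(
            gm.all_pairs_shortest_paths(PATH3)) == pytest.approx(5 / 6)
        iso = adj_from_edges(4, [(0, 1), (1, 2), (0, 2)])  # node 3 isolated
        e = gm.global_efficiency(gm.all_pairs_shortest_paths(iso))
        assert 0 < e < 1

    def test_local_efficiency_values(self):
        assert gm.local_efficiency(K4) == pytest.approx(1.0)
        assert gm.local_efficiency(STAR5) == 0.0
        assert gm.local_efficiency(CHORDED4) == pytest.approx(
            oracles.local_efficiency(CHORDED4))

    def test_degree_values(self):
        np.testing.assert_array_equal(gm.nodal_degree(STAR5), [4, 1, 1, 1, 1])
        np.testing.assert_array_equal(gm.nodal_degree(RING4), [2, 2, 2, 2])

    def test_nodal_efficiency_values(self):
        e = gm.nodal_efficiency(gm.all_pairs_shortest_paths(STAR4))
        assert e[0] == pytest.approx(1.0)
        assert e[1] == pytest.approx(2 / 3)
        iso = adj_from_edges(3, [(0, 1)])
        assert gm.nodal_efficiency(gm.all_pairs_shortest_paths(iso))[2] == 0.0

    def test_betweenness_values(self):
        np.testing.assert_allclose(gm.betweenness(PATH3), [0, 1, 0])
        assert gm.betweenness(STAR5)[0] == pytest.approx(6.0)  # (n-1)(n-2)/2

    def test_handshake_lemma(self):
        for seed in range(5):
            a = random_graph(15, 0.25, seed)
            assert gm.nodal_degree(a).sum() == a.sum()


class TestOracleEquivalence:
    """Fast implementations equal brute force on random 12-node graphs."""

    @pytest.mark.parametrize("seed", range(10))
    def test_all_metrics(self, seed):
        a = random_graph(12, 0.3, seed)
        if a.sum() == 0:
            pytest.skip("empty graph")
        c, cp = gm.clustering(a)
        np.testing.assert_allclose(c, oracles.clustering_per_node(a),
                                   atol=1e-12)
        d = gm.all_pairs_shortest_paths(a)
        assert gm.path_length(d)[0] == pytest.approx(oracles.path_length(a))
        assert gm.global_efficiency(d) == pytest.approx(
            oracles.global_efficiency(a))
        assert gm.local_efficiency(a) == pytest.approx(
            oracles.local_efficiency(a))
        np.testing.assert_allclose(
            gm.nodal_efficiency(d), oracles.nodal_efficiency(a), atol=1e-12)
        np.testing.assert_allclose(
            gm.betweenness(a), oracles.betweenness(a), atol=1e-9)

    def test_networkx_cross_check(self):
        """Independent library agrees on a moderate random graph."""
        import networkx as nx

        a = random_graph(25, 0.2, 123)
        g = nx.from_numpy_array(a)
        nx_bc = np.array([v for _, v in sorted(
            nx.betweenness_centrality(g, normalized=False).items())])
        np.testing.assert_allclose(gm.betweenness(a), nx_bc, atol=1e-9)
        nx_c = np.array([v for _, v in sorted(nx.clustering(g).items())])
        np.testing.assert_allclose(gm.clustering(a)[0], nx_c, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seed):
        """Relabeling nodes permutes every metric identically."""
        rng = np.random.default_rng(seed)
        a = random_graph(10, 0.35, seed)
        perm = rng.permutation(10)
        ap = a[np.ix_(perm, perm)]
        np.testing.assert_allclose(gm.clustering(ap)[0],
                                   gm.clustering(a)[0][perm], atol=1e-12)
        np.testing.assert_allclose(gm.betweenness(ap),
                                   gm.betweenness(a)[perm], atol=1e-9)
        np.testing.assert_array_equal(gm.nodal_degree(ap),
                                      gm.nodal_degree(a)[perm])


class TestRingLatticeClosedForm:
    @pytest.mark.parametrize("k", [4, 6, 10])
    def test_lattice_clustering(self, k):
        from fcnet.synth import make_ground_truth

        net = make_ground_truth(90, k, 0.0, seed=0)
        a = (net.weights > 0).astype(np.uint8)
        _, cp = gm.clustering(a)
        assert cp == pytest.approx(3 * (k - 2) / (4 * (k - 1)), abs=1e-12)


class TestNullModels:
    def test_triangle_returned_unchanged(self):
        tri = adj_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        with pytest.warns(UserWarning, match="no valid"):
            null = gm.rewire_null(tri, seed=0)
        np.testing.assert_array_equal(null, tri)

    def test_degree_sequence_preserved(self):
        a = random_graph(30, 0.2, 5)
        for seed in range(20):
            null = gm.rewire_null(a, seed=seed)
            np.testing.assert_array_equal(null.sum(0), a.sum(0))
            assert np.all(np.diag(null) == 0)
            np.testing.assert_array_equal(null, null.T)

    def test_fixed_seed_reproduces_ensemble(self):
        a = random_graph(30, 0.2, 6)
        cp1, lp1 = gm.null_ensemble(a, n_random=10, seed=3)
        cp2, lp2 = gm.null_ensemble(a, n_random=10, seed=3)
        np.testing.assert_array_equal(cp1, cp2)
        np.testing.assert_array_equal(lp1, lp2)

    def test_rewiring_destroys_lattice_clustering(self):
        """Rewired-lattice clustering falls to the random-graph level."""
        from fcnet.synth import make_ground_truth

        net = make_ground_truth(90, 10, 0.0, seed=0)
        a = (net.weights > 0).astype(np.uint8)
        null = gm.rewire_null(a, seed=1)
        _, cp_null = gm.clustering(null)
        er_cp = np.mean([gm.clustering(random_graph(90, 10 / 89, s))[1]
                         for s in range(100)])
        _, cp_latt = gm.clustering(a)
        assert cp_null < 0.3 * cp_latt
        assert cp_null - er_cp < 0.05


class TestSmallWorldIndices:
    def test_self_ensemble_is_unity(self):
        a = random_graph(20, 0.3, 7)
        _, cp = gm.clustering(a)
        lp, _ = gm.path_length(gm.all_pairs_shortest_paths(a))
        gamma = cp / cp
        lam = lp / lp
        assert gamma == lam == gamma / lam == 1.0

    def test_watts_strogatz_sigma_exceeds_criterion(self):
        from fcnet.synth import make_ground_truth

        net = make_ground_truth(90, 10, 0.1, seed=8)
        a = (net.weights > 0).astype(np.uint8)
        gamma, lam, sigma = gm.small_world_indices(a, n_random=100, seed=0)
        assert gamma > 1.5
        assert 0.9 < lam < 1.3
        assert sigma > 1.1

    def test_erdos_renyi_sigma_near_unity(self):
        sigmas = []
        for seed in range(20):
            a = random_graph(90, 0.2, seed + 100)
            _, _, s = gm.small_world_indices(a, n_random=20, seed=seed)
            sigmas.append(s)
        within = np.sum([(0.9 < s < 1.1) for s in sigmas])
        assert within >= 18  # ~95% of seeds


class TestCurvesAndAUC:
    def test_single_point_grid_zero_auc(self):
        assert gm.auc(np.array([3.0]), np.array([0.2])) == 0.0

    def test_constant_curve_auc(self):
        grid = np.round(np.arange(0.11, 0.301, 0.01), 10)
        vals = np.full(grid.size, 2.5)
        assert gm.auc(vals, grid) == pytest.approx(0.19 * 2.5)

    def test_default_grid_evaluates_20_points(self, rng):
        from fcnet.netcon import sparsity_grid

        z = rng.normal(size=(30, 30))
        z = 0.5 * (z + z.T)
        np.fill_diagonal(z, 0.0)
        conn = ConnectivityMatrix(
            z=z, roi_labels=tuple(f"R{i}" for i in range(30)))
        grid = sparsity_grid()
        sm = gm.metric_curves(conn, grid, n_random=3, seed=0)
        assert all(v.size == 20 for v in sm.global_curves.values())
        assert sm.nodal_curves["degree"].shape == (30, 20)
        assert set(sm.global_auc) == set(gm.GLOBAL_METRIC_NAMES)
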