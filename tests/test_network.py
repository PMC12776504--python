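"""OMST thresholding, graph metrics and laterality."""

import itertools

import numpy as np
import pytest

import networkx as nx
from pdcnet import network
from pdcnet.network import (laterality_index, li_group_test,
                            local_efficiency, node_degree, node_strength,
                            omst_binarize)


def brute_force_first_mst(sym):
    """Enumerate all spanning trees, minimizing total distance 1/w."""
    n = sym.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if sym[i, j] > 0]
    best, best_cost = None, np.inf
    for combo in itertools.combinations(edges, n - 1):
        g = nx.Graph(combo)
        if g.number_of_nodes() == n and nx.is_connected(g):
            cost = sum(1.0 / sym[i, j] for i, j in combo)
            if cost < best_cost:
                best, best_cost = combo, cost
    return {frozenset(e) for e in best}


def floyd_warshall(dist):
    d = dist.copy()
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def random_weighted_digraph(rng, n=6, density=0.5):
    W = rng.uniform(0.1, 1.0, (n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(W, 0.0)
    return W


class TestOmst:
    def test_three_node_first_mst_matches_brute_force(self):
        W = np.array([[0.0, 3.0, 1.0],
                      [3.0, 0.0, 2.0],
                      [1.0, 2.0, 0.0]])
        net = omst_binarize(W)
        first = {frozenset(e) for e in net.selection_trace[0]["edges"]}
        assert first == brute_force_first_mst(W)
        assert first == {frozenset((0, 1)), frozenset((1, 2))}

    @pytest.mark.parametrize("n", [4, 5])
    def test_first_mst_matches_brute_force_on_random_graphs(self, n, rng):
        for _ in range(10):
            sym = rng.uniform(0.1, 1.0, (n, n))
            sym = (sym + sym.T) / 2
            np.fill_diagonal(sym, 0.0)
            net = omst_binarize(sym)
            first = {frozenset(e) for e in net.selection_trace[0]["edges"]}
            assert first == brute_force_first_mst(sym)

    def test_output_spans_and_connects(self, rng):
        for _ in range(20):
            W = rng.uniform(0.05, 1.0, (7, 7))
            np.fill_diagonal(W, 0.0)
            net = omst_binarize(W)
            support = nx.Graph()
            support.add_nodes_from(range(7))
            for i, j in zip(*np.nonzero(net.adjacency)):
                support.add_edge(i, j)
            assert support.number_of_nodes() == 7
            assert nx.is_connected(support)
            # selected edges are a subset of positive-weight input edges
            assert np.all(W[net.adjacency] > 0)

    def test_tree_input_returned_whole(self):
        W = np.zeros((4, 4))
        for i, j, w in [(0, 1, 0.9), (1, 2, 0.8), (2, 3, 0.7)]:
            W[i, j] = W[j, i] = w
        net = omst_binarize(W)
        np.testing.assert_array_equal(net.adjacency, W > 0)
        assert len(net.selection_trace) == 1

    def test_disconnected_support_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            omst_binarize(W)

    def test_direction_restored_from_symmetrized_selection(self):
        W = np.zeros((3, 3))
        W[1, 0] = 0.8          # directed 0 -> 1 only
        W[0, 1] = 0.0
        W[2, 1] = 0.5
        W[1, 2] = 0.5
        net = omst_binarize(W)
        assert net.adjacency[1, 0] and not net.adjacency[0, 1]


class TestGraphMetrics:
    def test_single_edge_strengths(self):
        W = np.zeros((3, 3))
        W[1, 0] = 0.7          # edge a(0) -> b(1)
        assert node_strength(W, "out")[0] == pytest.approx(0.7)
        assert node_strength(W, "in")[1] == pytest.approx(0.7)
        assert node_strength(W, "out")[1] == 0
        assert node_strength(W, "total")[0] == pytest.approx(0.7)

    def test_symmetric_matrix_in_equals_out(self, rng):
        W = rng.uniform(0, 1, (5, 5))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        np.testing.assert_allclose(node_strength(W, "in"),
                                   node_strength(W, "out"))

    def test_strength_conservation(self, rng):
        W = random_weighted_digraph(rng)
        assert node_strength(W, "out").sum() == pytest.approx(
            node_strength(W, "in").sum())

    def test_unknown_direction_rejected(self, rng):
        with pytest.raises(ValueError):
            node_strength(random_weighted_digraph(rng), "sideways")

    def test_bidirectional_pair_degrees(self):
        A = np.zeros((2, 2), dtype=bool)
        A[0, 1] = A[1, 0] = True
        np.testing.assert_array_equal(node_degree(A), [2, 2])

    def test_empty_graph_zero_degree(self):
        np.testing.assert_array_equal(node_degree(np.zeros((4, 4),
                                                           dtype=bool)),
                                      np.zeros(4))

    def test_metrics_match_brute_force_on_random_graphs(self, rng):
        for _ in range(50):
            W = random_weighted_digraph(rng)
            n = W.shape[0]
            # strength oracle: double loop
            s_out = np.zeros(n)
            s_in = np.zeros(n)
            deg = np.zeros(n)
            for i in range(n):
                for j in range(n):
                    if W[i, j] > 0:
                        s_out[j] += W[i, j]
                        s_in[i] += W[i, j]
                        deg[i] += 1
                        deg[j] += 1
            np.testing.assert_allclose(node_strength(W, "out"), s_out,
                                       atol=1e-10)
            np.testing.assert_allclose(node_strength(W, "in"), s_in,
                                       atol=1e-10)
            np.testing.assert_array_equal(node_degree(W > 0), deg)
            # local efficiency oracle: Floyd-Warshall on each neighbourhood
            eff = np.zeros(n)
            for v in range(n):
                nbrs = sorted({j for j in range(n)
                               if W[j, v] > 0 or W[v, j] > 0} - {v})
                if len(nbrs) < 2:
                    continue
                k = len(nbrs)
                dist = np.full((k, k), np.inf)
                np.fill_diagonal(dist, 0.0)
                for a, s in enumerate(nbrs):
                    for b, t in enumerate(nbrs):
                        if a != b and W[t, s] > 0:   # s -> t
                            dist[a, b] = 1.0 / W[t, s]
                d = floyd_warshall(dist)
                acc = sum(1.0 / d[a, b] for a in range(k) for b in range(k)
                          if a != b and np.isfinite(d[a, b]) and d[a, b] > 0)
                eff[v] = acc / (k * (k - 1))
            np.testing.assert_allclose(local_efficiency(W), eff, atol=1e-10)

    def test_unit_triangle_local_efficiency_is_one(self):
        W = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(local_efficiency(W), 1.0)

    def test_isolated_and_leaf_nodes_have_zero_efficiency(self):
        W = np.zeros((4, 4))
        W[1, 0] = 0.5
        eff = local_efficiency(W)
        assert eff[0] == 0 and eff[1] == 0 and eff[2] == 0


class TestLaterality:
    def _weights(self, atlas, out_left, out_right, base="M1"):
        W = np.zeros((28, 28))
        i_l, i_r = atlas.index(f"{base}-L"), atlas.index(f"{base}-R")
        tgt = atlas.index("CG-L")
        tgt2 = atlas.index("CG-R")
        W[tgt, i_l] = out_left
        W[tgt2, i_r] = out_right
        return W

    def test_symmetric_outflow_gives_zero(self, atlas):
        res = laterality_index(self._weights(atlas, 2.0, 2.0), atlas)
        k = res.base_regions.index("M1")
        assert res.li[k] == pytest.approx(0.0)

    def test_fully_unilateral_gives_one(self, atlas):
        res = laterality_index(self._weights(atlas, 0.0, 2.0), atlas)
        k = res.base_regions.index("M1")
        assert res.li[k] == pytest.approx(1.0)

    def test_three_to_one_gives_half(self, atlas):
        res = laterality_index(self._weights(atlas, 1.0, 3.0), atlas)
        k = res.base_regions.index("M1")
        assert res.li[k] == pytest.approx(0.5)

    def test_zero_outflow_flagged_nan(self, atlas):
        res = laterality_index(np.zeros((28, 28)), atlas)
        assert np.all(np.isnan(res.li))

    def test_antisymmetric_under_hemisphere_swap(self, atlas, rng):
        u, a = rng.uniform(0.1, 2.0, 2)
        r1 = laterality_index(self._weights(atlas, a, u), atlas)
        r2 = laterality_index(self._weights(atlas, u, a), atlas)
        k = r1.base_regions.index("M1")
        assert r1.li[k] == pytest.approx(-r2.li[k])
        assert -1 <= r1.li[k] <= 1


class TestLiGroupTest:
    def test_all_zero_not_significant(self):
        res = li_group_test(np.zeros(10))
        assert not res["significant"] and res["p"] == 1.0

    def test_constant_nonzero_significant_by_construction(self):
        res = li_group_test(np.full(10, 0.5))
        assert res["significant"] and res["test_used"] == "degenerate"

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            li_group_test([0.1, 0.2])

    def test_clear_group_shift_detected(self, rng):
        x = rng.normal(0.5, 0.1, 22)
        assert li_group_test(x)["significant"]
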