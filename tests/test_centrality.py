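"""Centrality and bridge centrality against exhaustive path-enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from conftest import (
    as_network,
    brute_betweenness,
    brute_distance_matrix,
    random_weighted_graph,
)

from symptomnet import (
    bridge_centrality,
    bridge_table,
    centrality_table,
    node_centrality,
    scale_relative_to_max,
    shortest_path_lengths,
)


class TestShortestPaths:
    def test_single_edge_distance_is_reciprocal_weight(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        D = shortest_path_lengths(as_network(W)).to_numpy()
        assert D[0, 1] == pytest.approx(2.0)

    def test_detour_through_strong_edges_beats_weak_direct_edge(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.1
        W[0, 2] = W[2, 0] = 0.5
        W[2, 1] = W[1, 2] = 0.5
        D = shortest_path_lengths(as_network(W)).to_numpy()
        assert D[0, 1] == pytest.approx(4.0)  # 2 + 2 via node 3, not 10 direct

    def test_disconnected_components_are_infinitely_far(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.3
        W[2, 3] = W[3, 2] = 0.4
        D = shortest_path_lengths(as_network(W)).to_numpy()
        assert np.isinf(D[0, 2]) and np.isinf(D[1, 3])
        assert D[0, 1] == pytest.approx(1 / 0.3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_csgraph(self, seed):
        from scipy.sparse.csgraph import shortest_path as sp_shortest_path

        W = random_weighted_graph(seed)
        with np.errstate(divide="ignore"):
            L = np.where(W != 0, 1 / np.abs(W), np.inf)
        np.fill_diagonal(L, 0.0)
        expected = sp_shortest_path(np.where(np.isfinite(L), L, 0), method="D",
                                    unweighted=False, directed=False)
        got = shortest_path_lengths(as_network(W)).to_numpy()
        np.testing.assert_allclose(got, expected)


class TestNodeCentrality:
    def test_star_graph(self):
        # center 0 with 4 leaves, each |w| = 0.25
        W = np.zeros((5, 5))
        for leaf in range(1, 5):
            W[0, leaf] = W[leaf, 0] = 0.25
        cent = node_centrality(as_network(W))
        assert cent.loc["V1", "strength"] == pytest.approx(1.0)
        assert cent.loc["V1", "betweenness"] == pytest.approx(6.0)  # all 6 leaf pairs
        assert (cent.loc["V2":"V5", "betweenness"] == 0).all()
        # closeness of center: 4 leaves at distance 4 each
        assert cent.loc["V1", "closeness"] == pytest.approx(1 / 16)

    def test_complete_symmetric_graph_equalizes_all_indices(self):
        p = 4
        W = np.full((p, p), 0.3)
        np.fill_diagonal(W, 0.0)
        cent = node_centrality(as_network(W))
        for col in cent.columns:
            assert cent[col].nunique() == 1

    def test_mixed_sign_strength_vs_expected_influence(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[0, 2] = W[2, 0] = -0.3
        cent = node_centrality(as_network(W))
        assert cent.loc["V1", "strength"] == pytest.approx(0.6)
        assert cent.loc["V1", "expected_influence"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_betweenness_matches_brute_force(self, seed):
        W = random_weighted_graph(seed)
        got = node_centrality(as_network(W))["betweenness"].to_numpy()
        np.testing.assert_allclose(got, brute_betweenness(W), atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_distances_match_brute_force(self, seed):
        W = random_weighted_graph(seed, p=6)
        got = shortest_path_lengths(as_network(W)).to_numpy()
        np.testing.assert_allclose(got, brute_distance_matrix(W), atol=1e-8)

    def test_permutation_equivariance(self):
        W = random_weighted_graph(33, p=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(6)
        cent = node_centrality(as_network(W)).to_numpy()
        cent_p = node_centrality(as_network(W[np.ix_(perm, perm)])).to_numpy()
        np.testing.assert_allclose(cent_p, cent[perm], atol=1e-8)

    def test_adding_edge_never_decreases_strength(self):
        W = random_weighted_graph(8, p=5)
        W2 = W.copy()
        free = np.argwhere(np.triu(W == 0, k=1))
        i, j = free[0]
        W2[i, j] = W2[j, i] = 0.2
        s1 = node_centrality(as_network(W))["strength"]
        s2 = node_centrality(as_network(W2))["strength"]
        assert (s2 >= s1 - 1e-12).all()


class TestScaling:
    def test_divide_by_max_absolute(self):
        t = pd.DataFrame({"strength": [2.0, 1.0, 0.5]})
        np.testing.assert_allclose(scale_relative_to_max(t)["strength"], [1.0, 0.5, 0.25])

    def test_argmax_scales_to_one_and_equal_values_all_one(self):
        t = pd.DataFrame({"a": [3.0, 3.0], "b": [-2.0, 1.0]})
        out = scale_relative_to_max(t)
        assert (out["a"] == 1.0).all()
        assert out["b"].tolist() == [-1.0, 0.5]

    def test_zero_index_stays_zero_with_warning(self, caplog):
        import logging

        t = pd.DataFrame({"a": [0.0, 0.0]})
        with caplog.at_level(logging.WARNING):
            out = scale_relative_to_max(t)
        assert (out["a"] == 0).all()
        assert "identically zero" in caplog.text


class TestBridgeCentrality:
    def test_within_community_node_has_zero_bridge_strength(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5  # inside community A
        bt = bridge_centrality(as_network(W), ["A", "A", "B"])
        assert bt.loc["V1", "bridge_strength"] == 0
        assert bt.loc["V1", "bridge_expected_influence"] == 0

    def test_hand_enumerated_two_community_toy(self):
        # A1-A2 (0.5), A2-B1 (0.25)
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.25
        bt = bridge_centrality(as_network(W), ["A", "A", "B"])
        np.testing.assert_allclose(bt["bridge_strength"], [0.0, 0.25, 0.25])
        # A2 lies on the only A1<->B1 shortest path
        np.testing.assert_allclose(bt["bridge_betweenness"], [0.0, 1.0, 0.0])
        # bridge closeness: d(A1,B1) = 2+4 = 6; d(A2,B1) = 4; d(B1,*) = 6+4
        np.testing.assert_allclose(bt["bridge_closeness"], [1 / 6, 1 / 4, 1 / 10])

    def test_sign_reversal_flips_expected_influence_only(self):
        W = random_weighted_graph(4, p=6)
        comm = ["A", "A", "A", "B", "B", "B"]
        bt = bridge_centrality(as_network(W), comm)
        bt_neg = bridge_centrality(as_network(-W), comm)
        np.testing.assert_allclose(bt_neg["bridge_strength"], bt["bridge_strength"])
        np.testing.assert_allclose(
            bt_neg["bridge_expected_influence"], -bt["bridge_expected_influence"]
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_bridge_betweenness_matches_brute_force(self, seed):
        W = random_weighted_graph(seed)
        p = len(W)
        comm = ["A" if i < p // 2 else "B" for i in range(p)]
        got = bridge_centrality(as_network(W), comm)["bridge_betweenness"].to_numpy()
        expected = brute_betweenness(W, pair_filter=lambda s, t: comm[s] != comm[t])
        np.testing.assert_allclose(got, expected, atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_strength_conservation(self, seed):
        W = random_weighted_graph(seed, p=7)
        comm = ["A", "A", "A", "B", "B", "C", "C"]
        net = as_network(W, comm)
        strength = node_centrality(net)["strength"].to_numpy()
        bridge = bridge_centrality(net, comm)["bridge_strength"].to_numpy()
        same = np.equal.outer(comm, comm)
        within = (np.abs(W) * same).sum(axis=1)
        np.testing.assert_allclose(bridge + within, strength, atol=1e-12)

    def test_single_community_is_fatal(self):
        W = random_weighted_graph(1, p=4)
        with pytest.raises(ValueError, match="undefined"):
            bridge_centrality(as_network(W), ["A"] * 4)

    def test_unreachable_other_community_zeroes_bridge_closeness(self, caplog):
        import logging

        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5  # A component
        W[2, 3] = W[3, 2] = 0.5  # B component, disconnected from A
        with caplog.at_level(logging.WARNING):
            bt = bridge_centrality(as_network(W), ["A", "A", "B", "B"])
        assert (bt["bridge_closeness"] == 0).all()
        assert "cannot reach" in caplog.text


class TestOutputTables:
    def test_tables_ordered_by_scaled_expected_influence(self):
        W = random_weighted_graph(9, p=6)
        net = as_network(W, ["A", "A", "A", "B", "B", "B"])
        ct = centrality_table(net)
        assert list(ct["expected_influence_scaled"]) == sorted(
            ct["expected_influence_scaled"], reverse=True
        )
        assert ct["expected_influence_scaled"].abs().max() == pytest.approx(1.0)
        bt = bridge_table(net)
        assert list(bt["bridge_expected_influence_scaled"]) == sorted(
            bt["bridge_expected_influence_scaled"], reverse=True
        )
        assert set(ct.columns) >= {"community", "strength", "strength_scaled"}
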