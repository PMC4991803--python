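import numpy as np
import pandas as pd
import pytest

from connvuln import metrics
from connvuln.graph import ConnectomeGraph

from conftest import graph_from_matrix
from oracles import (
    betweenness_oracle,
    clustering_oracle,
    efficiency_oracle,
    nodal_efficiency_oracle,
    random_small_graph,
)


class TestEdgeDistance:
    @pytest.mark.parametrize("w,d", [(1, 1.0), (4, 0.25), (2, 0.5)])
    def test_inverse_weight(self, w, d):
        assert metrics.edge_distance(w) == d

    @pytest.mark.parametrize("w", [0, -1])
    def test_nonpositive_rejected(self, w):
        with pytest.raises(ValueError):
            metrics.edge_distance(w)

    def test_two_hop_path_ties_direct_edge(self):
        # a->b->c with weights (2,2) has length 1/2+1/2 = direct a->c weight 1
        W = np.array([[0, 2, 1], [0, 0, 2], [0, 0, 0]], dtype=float)
        D = metrics.distance_matrix(W, scale=1)
        assert D[0, 2] == 1.0
        # both co-minimal paths counted: the intermediate and the edge share
        B = metrics.betweenness(W)
        assert B[1] == pytest.approx(0.5)  # b carries half of the a->c traffic


class TestNodalBasic:
    def test_in_out_arithmetic(self):
        g = ConnectomeGraph.from_edges([("x", "n", 2), ("n", "y", 3)])
        row = metrics.nodal_basic(g, "n")
        assert row["D"] == 2 and row["D_in"] == 1 and row["D_out"] == 1
        assert row["Str_in"] == 2 and row["Str_out"] == 3
        assert row["AW_in"] == 2 and row["AW_out"] == 3
        assert row["Str_ratio"] == 1.5

    def test_isolated_node_zeroes_and_undefined_ratios(self):
        g = graph_from_matrix(np.zeros((3, 3)))
        row = metrics.nodal_basic(g, "n0")
        assert row["D"] == 0 and row["Str"] == 0
        assert np.isnan(row["D_ratio"]) and np.isnan(row["AW"])

    def test_complete_triangle_degrees(self, reciprocal_triangle):
        df = metrics.nodal_basic(reciprocal_triangle)
        assert (df["D_in"] == 2).all() and (df["D_out"] == 2).all()
        assert (df["Str"] == 4).all()
        assert (df["D"] == 2).all()  # reciprocal partners counted once

    def test_unknown_node_rejected(self, path_graph):
        with pytest.raises(KeyError):
            metrics.nodal_basic(path_graph, "zzz")


class TestClustering:
    def test_reciprocal_triangle_saturates(self, reciprocal_triangle):
        C = metrics.nodal_clustering(reciprocal_triangle.weight)
        assert C == pytest.approx([1.0, 1.0, 1.0])

    def test_star_center_no_neighbor_links(self, star5):
        assert metrics.nodal_clustering(star5.weight)[0] == 0.0

    def test_fewer_than_two_neighbors_gives_zero(self, path_graph):
        C = metrics.nodal_clustering(path_graph.weight)
        assert C[0] == 0.0 and C[2] == 0.0

    def test_weighted_triangle_matches_hand_formula(self):
        # 4 nodes, one directed triangle 0->1->2->0 with weights 1,2,4
        W = np.zeros((4, 4))
        W[0, 1], W[1, 2], W[2, 0] = 1, 2, 4
        W[3, 0] = 1  # spectator edge
        C = metrics.nodal_clustering(W)
        assert C == pytest.approx(clustering_oracle(W), abs=1e-12)
        # node 1: hand evaluation of the formula (two triangle orderings)
        cbrt = np.cbrt
        tri = 2 * cbrt(1 / 4) * cbrt(2 / 4) * cbrt(4 / 4)
        denom = 2 * (2 * 1 - 0)
        assert C[1] == pytest.approx(tri / denom)


class TestEfficiency:
    def test_complete_unit_digraph_is_one(self, reciprocal_triangle):
        assert metrics.efficiency(reciprocal_triangle.weight) == pytest.approx(1.0)

    def test_isolated_nodes_give_zero(self):
        assert metrics.efficiency(np.zeros((2, 2))) == 0.0

    def test_path_graph_hand_value(self, path_graph):
        assert metrics.efficiency(path_graph.weight) == pytest.approx(
            (1 + 0.5 + 1) / 6
        )
        assert metrics.nodal_efficiency(path_graph.weight)[0] == pytest.approx(0.75)

    def test_directions_of_nodal_efficiency(self, path_graph):
        W = path_graph.weight
        Ein = metrics.nodal_efficiency(W, direction="in")
        Eboth = metrics.nodal_efficiency(W, direction="both")
        assert Ein[2] == pytest.approx(0.75)
        assert Eboth == pytest.approx(
            (metrics.nodal_efficiency(W) + Ein) / 2
        )


class TestBetweenness:
    def test_path_graph_counts(self, path_graph):
        W = path_graph.weight
        B = metrics.betweenness(W)
        assert list(B) == [0.0, 1.0, 0.0]
        assert np.mean(B) == pytest.approx(1 / 3)
        eb = metrics.edge_betweenness(W)
        assert eb[(0, 1)] == 2.0  # paths a->b and a->c
        assert eb[(1, 2)] == 2.0

    def test_complete_digraph_all_zero(self, reciprocal_triangle):
        assert metrics.betweenness(reciprocal_triangle.weight) == pytest.approx(
            [0, 0, 0]
        )


class TestGlobalMetrics:
    def test_reciprocal_triangle_limits(self, reciprocal_triangle):
        gm = metrics.global_metrics(reciprocal_triangle)
        assert (gm.C, gm.E, gm.B) == pytest.approx((1.0, 1.0, 0.0))

    def test_empty_graph_on_three_nodes(self):
        gm = metrics.global_metrics(np.zeros((3, 3)))
        assert (gm.C, gm.E, gm.B) == (0.0, 0.0, 0.0)


class TestOracleEquivalence:
    """Implementation vs exhaustive enumeration on random small graphs."""

    @pytest.mark.parametrize("seed", range(8))
    def test_all_measures_match_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        for _ in range(5):
            W = random_small_graph(rng)
            B_o, EB_o = betweenness_oracle(W)
            assert metrics.betweenness(W) == pytest.approx(B_o, abs=1e-9)
            eb = metrics.edge_betweenness(W)
            for key, val in EB_o.items():
                assert eb[key] == pytest.approx(val, abs=1e-9)
            assert metrics.efficiency(W) == pytest.approx(
                efficiency_oracle(W), abs=1e-9
            )
            assert metrics.nodal_efficiency(W) == pytest.approx(
                nodal_efficiency_oracle(W), abs=1e-9
            )
            assert metrics.nodal_clustering(W) == pytest.approx(
                clustering_oracle(W), abs=1e-9
            )


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_and_signs(self, seed):
        W = random_small_graph(np.random.default_rng(seed), max_n=7)
        C = metrics.nodal_clustering(W)
        assert np.all((0 <= C) & (C <= 1))
        assert 0 <= metrics.efficiency(W) <= 1
        assert np.all(metrics.betweenness(W) >= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_efficiency_monotone_under_edge_removal(self, seed):
        W = random_small_graph(np.random.default_rng(100 + seed))
        scale = W.max()
        E = metrics.efficiency(W, scale)
        for i, j in np.argwhere(W > 0):
            W2 = W.copy()
            W2[i, j] = 0
            assert metrics.efficiency(W2, scale) <= E + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_relabeling_invariance(self, seed):
        rng = np.random.default_rng(200 + seed)
        W = random_small_graph(rng)
        perm = rng.permutation(W.shape[0])
        Wp = W[np.ix_(perm, perm)]
        gm, gmp = metrics.global_metrics(W), metrics.global_metrics(Wp)
        assert gm.C == pytest.approx(gmp.C, abs=1e-12)
        assert gm.E == pytest.approx(gmp.E, abs=1e-12)
        assert gm.B == pytest.approx(gmp.B, abs=1e-12)


class TestEuclideanLengths:
    def test_axis_and_2d_distances(self, small_meta):
        g = ConnectomeGraph.from_edges(
            [("AVAL", "PVCL", 1), ("AVAL", "AVAR", 1)],
            nodes=list(small_meta.index),
        )
        lengths = metrics.euclidean_edge_lengths(g, small_meta)
        assert lengths[("AVAL", "PVCL")] == pytest.approx(0.7)
        assert lengths[("AVAL", "AVAR")] == 0.0

    def test_345_triangle(self):
        meta = pd.DataFrame(
            {"name": ["a", "b"], "class": ["I", "I"],
             "soma_x": [0.0, 3.0], "soma_y": [0.0, 4.0]}
        ).set_index("name", drop=False)
        g = ConnectomeGraph.from_edges([("a", "b", 1)])
        assert metrics.euclidean_edge_lengths(g, meta)[("a", "b")] == 5.0

    def test_missing_positions_flagged_not_zero(self, small_meta):
        meta = small_meta.copy()
        meta.loc["DVC", "soma_x"] = np.nan
        g = ConnectomeGraph.from_edges(
            [("AVAL", "DVC", 1)], nodes=list(meta.index)
        )
        assert np.isnan(metrics.euclidean_edge_lengths(g, meta)[("AVAL", "DVC")])
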