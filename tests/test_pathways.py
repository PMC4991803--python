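import numpy as np
import pandas as pd
import pytest

from connvuln import pathways as pw
from connvuln.graph import ConnectomeGraph


class TestCollapseLR:
    def test_metadata_pairs_collapse_to_stem(self, small_meta):
        mapping = pw.collapse_lr(["AVAL", "AVAR", "DVC"], meta=small_meta)
        assert mapping["AVAL"] == "AVA" == mapping["AVAR"]
        assert mapping["DVC"] == "DVC"

    def test_suffix_heuristic_requires_sibling_in_roster(self):
        roster = ["RMDL", "RMDR", "VD01", "AVHL"]
        mapping = pw.collapse_lr(roster, roster=roster)
        assert mapping["RMDL"] == "RMD" == mapping["RMDR"]
        assert mapping["VD01"] == "VD01"
        assert mapping["AVHL"] == "AVHL"  # no AVHR in roster

    def test_asymmetric_partner_metadata_rejected(self, small_meta):
        meta = small_meta.copy()
        meta.loc["AVAR", "lr_partner"] = "PVCL"
        with pytest.raises(ValueError, match="asymmetric"):
            pw.collapse_lr(["AVAL"], meta=meta)

    def test_idempotence(self, small_meta):
        names = list(small_meta.index)
        first = pw.collapse_lr(names, meta=small_meta)
        again = pw.collapse_lr(sorted(set(first.values())))
        assert all(again[v] == v for v in set(first.values()))


def edge_frame(rows):
    return pd.DataFrame(rows, columns=["source", "target", "property", "grade"])


class TestAssemblePathways:
    def test_components_separate(self):
        edges = edge_frame(
            [("A", "B", "B", 7), ("B", "C", "B", 6), ("D", "E", "B", 8)]
        )
        paths = pw.assemble_pathways(edges)
        assert [set(p.nodes) for p in paths] == [{"A", "B", "C"}, {"D", "E"}]

    def test_reciprocal_pair_flagged(self):
        paths = pw.assemble_pathways(
            edge_frame([("A", "B", "B", 6), ("B", "A", "B", 6)])
        )
        assert len(paths) == 1
        assert all(e["reciprocal"] for e in paths[0].edges)

    def test_lr_collapsing_merges_parallel_edges(self, small_meta):
        edges = edge_frame(
            [("AVAL", "PVCL", "E", 9), ("AVAR", "PVCL", "B", 10)]
        )
        paths = pw.assemble_pathways(edges, meta=small_meta)
        assert len(paths) == 1
        (edge,) = paths[0].edges
        assert (edge["source"], edge["target"]) == ("AVA", "PVC")
        assert len(edge["supports"]) == 2
        assert edge["properties"] == {"E", "B"}

    def test_empty_input_gives_no_pathways(self):
        assert pw.assemble_pathways(edge_frame([])) == []

    def test_node_sets_partition(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"N{a}", f"N{b}", "B", 6)
            for a, b in rng.integers(0, 20, size=(30, 2))
            if a != b
        ]
        paths = pw.assemble_pathways(edge_frame(rows))
        seen = [n for p in paths for n in p.nodes]
        assert len(seen) == len(set(seen))
        assert sum(p.n_supporting_synapses for p in paths) == len(
            {(r[0], r[1]) for r in rows}
        )


class TestAnnotation:
    def test_inhibitory_edge_from_metadata(self, small_meta):
        paths = pw.assemble_pathways(
            edge_frame([("VD01", "DVC", "B", 13), ("DVC", "PVCL", "B", 7)]),
            meta=small_meta,
        )
        (p,) = paths
        signs = {(e["source"], e["target"]): e["inhibitory"] for e in p.edges}
        assert signs[("VD01", "DVC")] is True
        assert signs[("DVC", "PVC")] is False

    def test_missing_class_tagged_unknown(self, small_meta):
        paths = pw.assemble_pathways(
            edge_frame([("DVC", "XX99", "B", 6)]), meta=small_meta
        )
        assert paths[0].node_classes["XX99"] == "unknown"
        assert paths[0].node_classes["DVC"] == "I"


class TestLongRange:
    @staticmethod
    def chain_graph(positions):
        names = [f"n{i}" for i in range(len(positions))]
        meta = pd.DataFrame(
            {"name": names, "class": "I", "soma_x": positions}
        ).set_index("name", drop=False)
        edges = [(names[i], names[i + 1], 1) for i in range(len(names) - 1)]
        # add extra local edges so quantiles are over many lengths
        edges += [(names[i + 1], names[i], 1) for i in range(len(names) - 1)]
        return ConnectomeGraph.from_edges(edges, nodes=names), meta, names

    def test_all_equal_lengths_no_long_range(self):
        g, meta, names = self.chain_graph(np.linspace(0, 1, 11))
        crit_edges = pd.DataFrame(
            {"source": [names[0]], "target": [names[1]]}
        )
        res = pw.long_range_fraction(crit_edges, g, meta, 0.90)
        assert res["fraction"] == 0.0

    def test_constructed_three_of_ten_above_quantile(self):
        # 30 local edges of length 1 and 3 of length 10; critical set has
        # 10 edges of which exactly the 3 long ones exceed the 0.9 quantile
        names = [f"m{i}" for i in range(40)]
        pos = {n: float(i) for i, n in enumerate(names)}
        edges = [(names[i], names[i + 1], 1) for i in range(30)]
        long_pairs = [(names[0], names[10]), (names[5], names[15]),
                      (names[20], names[30])]
        edges += [(u, v, 1) for u, v in long_pairs]
        meta = pd.DataFrame(
            {"name": names, "class": "I", "soma_x": [pos[n] for n in names]}
        ).set_index("name", drop=False)
        g = ConnectomeGraph.from_edges(edges, nodes=names)
        crit = pd.DataFrame(
            [(names[i], names[i + 1]) for i in range(7)] + long_pairs,
            columns=["source", "target"],
        )
        res = pw.long_range_fraction(crit, g, meta, 0.90)
        assert res["fraction"] == pytest.approx(0.30)
        assert res["n_edges_used"] == 10

    def test_missing_positions_excluded_and_counted(self):
        g, meta, names = self.chain_graph(np.linspace(0, 1, 5))
        meta.loc["n0", "soma_x"] = np.nan
        crit = pd.DataFrame(
            {"source": ["n0", "n1"], "target": ["n1", "n2"]}
        )
        res = pw.long_range_fraction(crit, g, meta, 0.5)
        assert res["n_missing_positions"] == 1
        assert res["n_edges_used"] == 1


class TestNeighborProfile:
    def make_graph_meta(self):
        names = ["X", "a", "b", "c", "d"]
        edges = [("a", "X", 1), ("X", "b", 1), ("c", "X", 1)]
        g = ConnectomeGraph.from_edges(edges, nodes=names)
        gap = np.zeros((5, 5))
        gap[0, 4] = gap[4, 0] = 1  # X -- d gap junction
        g = ConnectomeGraph(names, g.chem, gap)
        meta = pd.DataFrame(
            {
                "name": names,
                "class": "I",
                "functions": [
                    "",
                    "locomotion",
                    "locomotion;chemotaxis",
                    "locomotion",
                    "",
                ],
            }
        ).set_index("name", drop=False)
        return g, meta

    def test_counts_ranked_and_split_by_provenance(self):
        g, meta = self.make_graph_meta()
        prof = pw.neighbor_function_profile(g, "X", meta)
        top = prof.iloc[0]
        assert top["category"] == "movement" and top["total"] == 3
        unknown = prof.set_index("category").loc["unknown"]
        assert unknown["gap"] == 1  # unannotated gap partner d

    def test_no_annotated_partners_all_unknown(self):
        g, meta = self.make_graph_meta()
        meta["functions"] = ""
        prof = pw.neighbor_function_profile(g, "X", meta).set_index("category")
        assert prof.loc["unknown", "total"] == 4
        assert prof.drop("unknown")["total"].sum() == 0

    def test_unknown_node_rejected(self):
        g, meta = self.make_graph_meta()
        with pytest.raises(KeyError):
            pw.neighbor_function_profile(g, "nope", meta)


class TestPlot:
    def test_layout_figure_written(self, tmp_path, small_meta):
        paths = pw.assemble_pathways(
            edge_frame([("VD01", "DVC", "B", 13), ("DVC", "PVCL", "B", 7)]),
            meta=small_meta,
        )
        out = tmp_path / "pathways.svg"
        pw.plot_pathways(paths, small_meta, out)
        assert out.exists() and out.stat().st_size > 0
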