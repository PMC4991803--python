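"""Model/Results interface to the full vulnerability analysis.

:class:`ConnectomeVulnerability` is built from a connectome (plus
optional neuron metadata) and analysis options; :meth:`fit` runs the
exhaustive node and edge attack sweeps and the criticality criteria
and returns a :class:`VulnerabilityResults` carrying the vulnerability
tables, the critical sets with their thresholds and sigma grades, and
diagnostics.  Pathway assembly, group comparisons, correlations and
the long-range bias hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import criticality as crit
from .attack import run_edge_attacks, run_node_attacks
from .graph import ConnectomeGraph
from .metrics import (
    GlobalMetrics,
    MetricOptions,
    edge_metric_table,
    global_metrics,
    node_metric_table,
)

__all__ = ["ConnectomeVulnerability", "VulnerabilityResults"]


class ConnectomeVulnerability:
    """Vulnerability analysis of a weighted directed connectome.

    Parameters
    ----------
    graph
        The intact connectome.
    meta
        Optional per-neuron metadata (classes, birth times, soma
        positions, L/R partners, function labels, inhibitory flags).
    clustering, efficiency_direction
        Metric formulation toggles (see :class:`MetricOptions`).
    node_multiplier
        SD multiplier of the neuron criticality criterion (default 3).
    sd_ddof
        Degrees-of-freedom correction of the SD estimator (1 = sample
        SD, the default).
    grade_method
        ``"floor"`` (default) or ``"round"`` for integer sigma grades.
    long_range_quantile
        Connectome-wide soma-distance quantile defining "long-range".
    """

    def __init__(
        self,
        graph: ConnectomeGraph,
        meta: pd.DataFrame | None = None,
        *,
        clustering: str = "fagiolo",
        efficiency_direction: str = "out",
        node_multiplier: float = 3.0,
        sd_ddof: int = 1,
        grade_method: str = "floor",
        long_range_quantile: float = 0.90,
    ) -> None:
        self.graph = graph
        self.meta = meta
        self.options = MetricOptions(
            clustering=clustering, efficiency_direction=efficiency_direction
        )
        self.node_multiplier = float(node_multiplier)
        self.sd_ddof = int(sd_ddof)
        self.grade_method = grade_method
        self.long_range_quantile = float(long_range_quantile)
        if meta is not None and "class" in meta.columns:
            missing = [n for n in graph.nodes if n not in meta.index]
            if missing:
                raise ValueError(
                    f"metadata misses {len(missing)} graph neuron(s), "
                    f"e.g. {missing[:5]}"
                )

    # ------------------------------------------------------------------
    @classmethod
    def from_edge_lists(cls, chem_path, gap_path, meta_path=None, **kwargs):
        """Build the model straight from chemical/gap edge lists on disk."""
        from . import io

        chem = io.read_edge_list(chem_path, "chemical")
        gap = io.read_edge_list(gap_path, "gap")
        meta = io.read_metadata(meta_path) if meta_path else None
        roster = list(meta["name"]) if meta is not None else None
        graph = io.build_combined_graph(chem, gap, roster=roster)
        return cls(graph, meta, **kwargs)

    @classmethod
    def from_synthetic(cls, spec=None, seed: int = 0, **kwargs):
        """Build the model from a synthetic connectome draw."""
        from .synth import SynthSpec, generate_connectome

        if spec is None:
            spec = SynthSpec(seed=seed)
        graph, meta, key = generate_connectome(spec)
        model = cls(graph, meta, **kwargs)
        model.synthetic_key = key
        return model

    # ------------------------------------------------------------------
    def fit(self, targets: str = "both") -> "VulnerabilityResults":
        """Run the attack sweeps and criticality criteria.

        ``targets`` selects ``"nodes"``, ``"edges"`` or ``"both"``.
        """
        if targets not in ("nodes", "edges", "both"):
            raise ValueError(f"targets must be nodes, edges or both, got {targets!r}")
        intact = global_metrics(self.graph, self.options)
        res = VulnerabilityResults(self, intact)

        if targets in ("nodes", "both"):
            res.node_table = run_node_attacks(self.graph, self.options, intact)
            res.critical_nodes, res.critical_node_union = crit.node_critical_set(
                res.node_table,
                self.node_multiplier,
                ddof=self.sd_ddof,
                grade_method=self.grade_method,
            )
        if targets in ("edges", "both"):
            res.edge_table = run_edge_attacks(self.graph, self.options, intact)
            res.change_points = self._change_points(res.edge_table)
            computable = {p: k for p, k in res.change_points.items() if k is not None}
            if computable:
                res.edge_multiplier = float(crit.edge_criterion(computable))
            else:
                # histograms too narrow for a change point: fall back to
                # the node criterion so the edge analysis still completes
                res.edge_multiplier = self.node_multiplier
            res.critical_edges, res.critical_edge_union = crit.edge_critical_set(
                res.edge_table,
                res.edge_multiplier,
                ddof=self.sd_ddof,
                grade_method=self.grade_method,
            )
        return res

    def _change_points(self, edge_table: pd.DataFrame) -> dict[str, int | None]:
        points: dict[str, int | None] = {}
        for p in crit.PROPERTIES:
            hist = crit.sd_histogram(
                edge_table[f"V_{p}"],
                ddof=self.sd_ddof,
                grade_method=self.grade_method,
            )
            try:
                points[p] = crit.changepoint(hist)
            except ValueError:
                points[p] = None
        return points


class VulnerabilityResults:
    """Fitted results: vulnerability tables, critical sets, diagnostics."""

    def __init__(self, model: ConnectomeVulnerability, intact: GlobalMetrics):
        self.model = model
        self.intact = intact
        self.node_table: pd.DataFrame | None = None
        self.edge_table: pd.DataFrame | None = None
        self.critical_nodes: dict[str, crit.CriticalSet] | None = None
        self.critical_node_union: list | None = None
        self.change_points: dict[str, int | None] | None = None
        self.edge_multiplier: float | None = None
        self.critical_edges: dict[str, crit.CriticalSet] | None = None
        self.critical_edge_union: list | None = None

    # ------------------------------------------------------------------
    # derived tables
    # ------------------------------------------------------------------
    def critical_node_frame(self) -> pd.DataFrame:
        """Critical neurons with per-property sigma grades (one row each)."""
        return self._critical_frame(self.critical_nodes, self.critical_node_union)

    def critical_edge_frame(self) -> pd.DataFrame:
        """Critical synapses with per-property sigma grades (one row each)."""
        return self._critical_frame(self.critical_edges, self.critical_edge_union)

    @staticmethod
    def _critical_frame(sets, union) -> pd.DataFrame:
        if sets is None:
            raise ValueError("this target kind was not fitted")
        rows = []
        for target in union:
            row: dict = {}
            if isinstance(target, tuple):
                row["source"], row["target"] = target
            else:
                row["target"] = target
            for p, cs in sets.items():
                row[f"grade_{p}"] = cs.members.get(target, np.nan)
            rows.append(row)
        cols = (
            ["source", "target"]
            if union and isinstance(union[0], tuple)
            else ["target"]
        )
        return pd.DataFrame(rows, columns=cols + [f"grade_{p}" for p in sets])

    def critical_edge_long(self) -> pd.DataFrame:
        """Critical synapses in long form: one row per (edge, property)."""
        if self.critical_edges is None:
            raise ValueError("edge attacks were not fitted")
        rows = []
        for p, cs in self.critical_edges.items():
            for (u, v), grade in cs.members.items():
                rows.append(
                    {"source": u, "target": v, "property": p, "grade": grade}
                )
        return pd.DataFrame(rows, columns=["source", "target", "property", "grade"])

    # ------------------------------------------------------------------
    # downstream analyses
    # ------------------------------------------------------------------
    def pathways(self, property: str | None = "B"):
        """Assemble critical synapses into L/R-collapsed pathways.

        ``property`` restricts to one vulnerability measure (default
        ``"B"``, whose pathways the analysis emphasizes); ``None``
        uses the whole critical union.
        """
        from .pathways import assemble_pathways

        edges = self.critical_edge_long()
        if property is not None:
            edges = edges[edges["property"] == property]
        return assemble_pathways(
            edges.reset_index(drop=True),
            meta=self.model.meta,
            roster=self.model.graph.nodes,
        )

    def group_comparison(self, kind: str = "nodes") -> pd.DataFrame:
        """Mann-Whitney comparison of critical vs noncritical components.

        For nodes the factors are D, Str, AW, C_i, E_i, B_i of the
        intact network; for edges, weight and EBC.
        """
        if kind == "nodes":
            table = node_metric_table(self.model.graph, self.model.options)
            members = set(self.critical_node_union or [])
            mask = np.array([n in members for n in table.index])
            factors = ["D", "Str", "AW", "C_i", "E_i", "B_i"]
        elif kind == "edges":
            table = edge_metric_table(self.model.graph, self.model.meta)
            table = table.set_index(["source", "target"])
            members = set(self.critical_edge_union or [])
            mask = np.array([e in members for e in table.index])
            factors = ["weight", "EBC"]
        else:
            raise ValueError(f"kind must be nodes or edges, got {kind!r}")
        rows = {
            f: crit.group_comparison(table[f].to_numpy(), mask) for f in factors
        }
        return pd.DataFrame(rows).T.rename_axis("factor")

    def correlations(self, kind: str = "nodes", method: str = "spearman"):
        """Correlation of intact properties with signed vulnerabilities."""
        sv_cols = ["sV_C", "sV_E", "sV_B"]
        if kind == "nodes":
            props = node_metric_table(self.model.graph, self.model.options)[
                ["D", "Str", "AW", "C_i", "E_i", "B_i"]
            ]
            sv = self.node_table[sv_cols]
        elif kind == "edges":
            props = edge_metric_table(self.model.graph).set_index(
                ["source", "target"]
            )[["weight", "EBC"]]
            sv = self.edge_table[sv_cols]
        else:
            raise ValueError(f"kind must be nodes or edges, got {kind!r}")
        return crit.property_vulnerability_correlation(props, sv, method=method)

    def long_range(self, threshold_quantile: float | None = None) -> dict:
        """Long-range bias of the critical synapses (soma distances)."""
        from .pathways import long_range_fraction

        if self.model.meta is None:
            raise ValueError("long-range analysis needs soma positions (metadata)")
        q = threshold_quantile or self.model.long_range_quantile
        return long_range_fraction(
            self.critical_edge_frame(), self.model.graph, self.model.meta, q
        )

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary of the fitted analysis."""
        g = self.model.graph
        lines = [
            "Connectome vulnerability analysis",
            "=" * 50,
            f"Neurons: {g.n_nodes}   Synaptic connections: {g.n_edges}",
            f"Contacts: chemical {int(g.chem.sum())}, gap {int(g.gap.sum())}",
            (
                f"Intact network:  C = {self.intact.C:.4f}   "
                f"E = {self.intact.E:.4f}   B = {self.intact.B:.2f}"
            ),
        ]
        if self.critical_nodes is not None:
            counts = {p: len(cs) for p, cs in self.critical_nodes.items()}
            lines += [
                "-" * 50,
                (
                    f"Critical neurons (> mean + "
                    f"{self.model.node_multiplier:g} SD): "
                    + "  ".join(f"V_{p}: {c}" for p, c in counts.items())
                    + f"  union: {len(self.critical_node_union)}"
                ),
            ]
            for t in self.critical_node_union:
                grades = "  ".join(
                    f"{p}:{self.critical_nodes[p].members[t]}s"
                    for p in self.critical_nodes
                    if t in self.critical_nodes[p].members
                )
                lines.append(f"  {t:<10} {grades}")
        if self.critical_edges is not None:
            cp = {
                p: (k if k is not None else "-")
                for p, k in (self.change_points or {}).items()
            }
            counts = {p: len(cs) for p, cs in self.critical_edges.items()}
            lines += [
                "-" * 50,
                (
                    "Change points: "
                    + "  ".join(f"V_{p}: {v}" for p, v in cp.items())
                    + f"   governing multiplier: {self.edge_multiplier:g} SD"
                ),
                (
                    "Critical synapses: "
                    + "  ".join(f"V_{p}: {c}" for p, c in counts.items())
                    + f"  union: {len(self.critical_edge_union)}"
                ),
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        fitted = [
            k
            for k, v in (
                ("nodes", self.node_table),
                ("edges", self.edge_table),
            )
            if v is not None
        ]
        return f"<VulnerabilityResults fitted={fitted}>"
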