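"""Assembly of critical synapses into circuit-level pathways.

Bilaterally symmetric neuron pairs (AVAL/AVAR and the like) are
collapsed to their shared stem (AVA), the critical synapses are drawn
as a directed graph over the collapsed names, and each weakly
connected component of that graph is reported as one *pathway* with
direction, reciprocity, excitatory/inhibitory sign and S/I/M class
annotations.  A neighbor-function profile helps suggest roles for
neurons whose biological function is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph import ConnectomeGraph

__all__ = [
    "Pathway",
    "collapse_lr",
    "assemble_pathways",
    "annotate_pathway",
    "long_range_fraction",
    "neighbor_function_profile",
    "plot_pathways",
    "DEFAULT_FUNCTION_LEXICON",
]


@dataclass
class Pathway:
    """One weakly connected component of the collapsed critical-edge graph."""

    component_id: int
    nodes: list[str]
    node_classes: dict[str, str] = field(default_factory=dict)
    # each edge: dict(source, target, reciprocal, inhibitory, properties,
    #                 supports=[(orig_source, orig_target, property, grade), ...])
    edges: list[dict] = field(default_factory=list)

    @property
    def n_supporting_synapses(self) -> int:
        return sum(len(e["supports"]) for e in self.edges)

    def to_records(self) -> list[dict]:
        rows = []
        for e in self.edges:
            rows.append(
                {
                    "component": self.component_id,
                    "source": e["source"],
                    "target": e["target"],
                    "source_class": self.node_classes.get(e["source"], "unknown"),
                    "target_class": self.node_classes.get(e["target"], "unknown"),
                    "reciprocal": e["reciprocal"],
                    "inhibitory": e["inhibitory"],
                    "properties": ";".join(sorted(e["properties"])),
                    "n_supports": len(e["supports"]),
                }
            )
        return rows


def collapse_lr(
    names,
    meta: pd.DataFrame | None = None,
    roster=None,
) -> dict[str, str]:
    """Map each neuron name to its left/right-collapsed stem.

    Metadata ``lr_partner`` columns take precedence; as a fallback a
    trailing L or R is stripped only when the opposite-suffix sibling
    exists in the roster (so AVAL -> AVA because AVAR exists, but VD01
    stays VD01).  Partner records must be symmetric.
    """
    names = list(names)
    roster = set(roster) if roster is not None else set(names)
    mapping: dict[str, str] = {}

    partners: dict[str, str] = {}
    if meta is not None and "lr_partner" in meta.columns:
        for name, partner in meta["lr_partner"].dropna().items():
            if not partner:
                continue
            if partner in meta.index:
                back = meta.at[partner, "lr_partner"]
                if pd.isna(back) or back != name:
                    raise ValueError(
                        f"asymmetric L/R partnership: {name} -> {partner} -> {back}"
                    )
            partners[str(name)] = str(partner)
        roster = roster | set(partners) | set(partners.values())

    def stem_of(a: str, b: str) -> str:
        # common prefix of a paired pair, trimming a trailing L/R if left over
        k = 0
        while k < min(len(a), len(b)) and a[k] == b[k]:
            k += 1
        stem = a[:k]
        return stem if stem else a

    for name in names:
        if name in partners:
            mapping[name] = stem_of(name, partners[name])
        elif name.endswith(("L", "R")) and len(name) > 1:
            sibling = name[:-1] + ("R" if name.endswith("L") else "L")
            mapping[name] = name[:-1] if sibling in roster else name
        else:
            mapping[name] = name
    return mapping


def assemble_pathways(
    critical_edges: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    roster=None,
) -> list[Pathway]:
    """Group critical synapses into pathways after L/R collapsing.

    ``critical_edges`` needs columns ``source`` and ``target``;
    optional columns ``property`` and ``grade`` are carried through as
    edge support annotations.  Returns weakly connected components of
    the collapsed directed graph, largest first; reciprocal collapsed
    pairs are flagged on both directions.
    """
    if critical_edges.empty:
        return []
    names = pd.unique(
        pd.concat([critical_edges["source"], critical_edges["target"]])
    )
    mapping = collapse_lr(names, meta=meta, roster=roster)

    G = nx.DiGraph()
    for row in critical_edges.itertuples(index=False):
        u, v = mapping[row.source], mapping[row.target]
        if u == v:
            continue  # an L->R synapse within one pair collapses away
        prop = getattr(row, "property", None)
        grade = getattr(row, "grade", None)
        support = (row.source, row.target, prop, grade)
        if G.has_edge(u, v):
            G[u][v]["supports"].append(support)
            if prop:
                G[u][v]["properties"].add(prop)
        else:
            G.add_edge(
                u, v, supports=[support], properties={prop} if prop else set()
            )

    components = sorted(
        nx.weakly_connected_components(G), key=lambda c: (-len(c), sorted(c))
    )
    pathways = []
    for cid, comp in enumerate(components):
        sub = G.subgraph(comp)
        edges = []
        for u, v, data in sub.edges(data=True):
            edges.append(
                {
                    "source": u,
                    "target": v,
                    "reciprocal": sub.has_edge(v, u),
                    "inhibitory": False,  # filled by annotate_pathway
                    "properties": set(data["properties"]),
                    "supports": list(data["supports"]),
                }
            )
        pw = Pathway(component_id=cid, nodes=sorted(comp), edges=edges)
        if meta is not None:
            annotate_pathway(pw, meta, mapping)
        pathways.append(pw)
    return pathways


def _collapsed_meta_lookup(meta: pd.DataFrame, mapping: dict[str, str]):
    """Collapsed name -> list of original metadata rows."""
    groups: dict[str, list] = {}
    for name in meta.index:
        groups.setdefault(mapping.get(name, name), []).append(name)
    return groups


def annotate_pathway(
    pathway: Pathway, meta: pd.DataFrame, mapping: dict[str, str] | None = None
) -> Pathway:
    """Attach S/I/M class tags and excitatory/inhibitory edge signs.

    A collapsed edge is inhibitory when any supporting original synapse
    originates from a neuron whose ``inhibitory_targets`` metadata
    covers the original target (``*`` marks all chemical outputs as
    inhibitory, as for GABAergic classes).  Missing classes are tagged
    ``unknown``.
    """
    if mapping is None:
        all_names = set(meta.index)
        mapping = collapse_lr(sorted(all_names), meta=meta)
    groups = _collapsed_meta_lookup(meta, mapping)

    for node in pathway.nodes:
        classes = {
            str(meta.at[orig, "class"])
            for orig in groups.get(node, [])
            if "class" in meta.columns and pd.notna(meta.at[orig, "class"])
        }
        pathway.node_classes[node] = classes.pop() if len(classes) == 1 else (
            "/".join(sorted(classes)) if classes else "unknown"
        )

    has_inhib = "inhibitory_targets" in meta.columns
    for edge in pathway.edges:
        inhibitory = False
        for orig_u, orig_v, _, _ in edge["supports"]:
            if has_inhib and orig_u in meta.index:
                spec = meta.at[orig_u, "inhibitory_targets"]
                if pd.notna(spec) and spec != "":
                    targets = {t.strip() for t in str(spec).split(";")}
                    if "*" in targets or orig_v in targets:
                        inhibitory = True
        edge["inhibitory"] = inhibitory
    return pathway


def long_range_fraction(
    critical_edges: pd.DataFrame,
    graph: ConnectomeGraph,
    meta: pd.DataFrame,
    threshold_quantile: float = 0.90,
) -> dict:
    """Share of critical synapses that are long-range soma-to-soma links.

    "Long-range" means the straight-line (Euclidean) soma distance
    exceeds the given quantile of all connectome edge lengths, so the
    connectome-wide baseline fraction is about ``1 - quantile``.  Edges
    with missing coordinates are excluded and counted.
    """
    from .metrics import euclidean_edge_lengths

    lengths = euclidean_edge_lengths(graph, meta)
    all_lengths = np.array([v for v in lengths.values() if np.isfinite(v)])
    if all_lengths.size == 0:
        raise ValueError("no finite soma distances available")
    threshold = float(np.quantile(all_lengths, threshold_quantile))

    flags: dict[tuple[str, str], bool] = {}
    missing = 0
    for row in critical_edges.itertuples(index=False):
        d = lengths.get((row.source, row.target), np.nan)
        if not np.isfinite(d):
            missing += 1
            continue
        flags[(row.source, row.target)] = bool(d > threshold)
    n_flagged = sum(flags.values())
    n_used = len(flags)
    return {
        "fraction": n_flagged / n_used if n_used else np.nan,
        "n_long_range": n_flagged,
        "n_edges_used": n_used,
        "n_missing_positions": missing,
        "threshold": threshold,
        "threshold_quantile": threshold_quantile,
        "baseline_fraction": float(np.mean(all_lengths > threshold)),
        "flags": flags,
    }


#: Keyword lexicon mapping free-text function labels to the four
#: neighbor-profile categories.  Editable/overridable by the user.
DEFAULT_FUNCTION_LEXICON: dict[str, str] = {
    "locomotion": "movement",
    "movement": "movement",
    "motor": "movement",
    "touch": "movement",
    "withdrawal": "movement",
    "pioneer": "development",
    "pioneering": "development",
    "development": "development",
    "growth": "development",
    "guidance": "development",
    "chemotaxis": "integration",
    "chemosensation": "integration",
    "integration": "integration",
    "aerotaxis": "integration",
    "feeding": "integration",
    "immunity": "integration",
    "unknown": "unknown",
}

CATEGORIES = ("movement", "development", "integration", "unknown")


def _categorize(label: str, lexicon: dict[str, str]) -> str:
    low = label.lower()
    for key, cat in lexicon.items():
        if key in low:
            return cat
    return "unknown"


def neighbor_function_profile(
    graph: ConnectomeGraph,
    node: str,
    meta: pd.DataFrame,
    lexicon: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Function categories of a neuron's synaptic partners, ranked by count.

    Every in- or out-partner contributes its function labels, mapped
    to four categories (movement/locomotion, pioneering/development,
    chemical-integration, unknown), split by synapse provenance
    (chemical vs gap).  Partners without annotations count as unknown.
    """
    lexicon = lexicon or DEFAULT_FUNCTION_LEXICON
    k = graph.index(node)
    counts = {cat: {"chemical": 0, "gap": 0} for cat in CATEGORIES}
    for layer_name, layer in (("chemical", graph.chem), ("gap", graph.gap)):
        partners = np.nonzero((layer[k, :] > 0) | (layer[:, k] > 0))[0]
        for p in partners:
            pname = graph.nodes[p]
            labels: list[str] = []
            if (
                pname in meta.index
                and "functions" in meta.columns
                and pd.notna(meta.at[pname, "functions"])
                and str(meta.at[pname, "functions"]).strip()
            ):
                labels = [
                    s.strip()
                    for s in str(meta.at[pname, "functions"]).split(";")
                    if s.strip()
                ]
            if not labels:
                counts["unknown"][layer_name] += 1
                continue
            for label in labels:
                counts[_categorize(label, lexicon)][layer_name] += 1
    df = pd.DataFrame(
        [
            {
                "category": cat,
                "chemical": counts[cat]["chemical"],
                "gap": counts[cat]["gap"],
                "total": counts[cat]["chemical"] + counts[cat]["gap"],
            }
            for cat in CATEGORIES
        ]
    ).sort_values(["total", "category"], ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)


def plot_pathways(pathways, meta: pd.DataFrame | None = None, path=None):
    """Simple layout figure: pathway nodes along the anterior-posterior axis.

    Nodes are placed by soma position (x) and pathway membership (y);
    inhibitory edges are dashed, reciprocal ones double-headed.
    Returns the matplotlib figure; writes SVG/PNG when ``path`` given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 1.5 + 1.2 * max(len(pathways), 1)))
    pos: dict[str, tuple[float, float]] = {}
    for row, pw in enumerate(pathways):
        for k, node in enumerate(pw.nodes):
            x = np.nan
            if meta is not None and "soma_x" in meta.columns:
                originals = [n for n in meta.index
                             if n == node or n.rstrip("LR") == node]
                vals = [meta.at[n, "soma_x"] for n in originals]
                vals = [v for v in vals if pd.notna(v)]
                if vals:
                    x = float(np.mean(vals))
            if np.isnan(x):
                x = k / max(len(pw.nodes) - 1, 1)
            pos[node] = (x, -row)
        for edge in pw.edges:
            (x0, y0), (x1, y1) = pos[edge["source"]], pos[edge["target"]]
            style = "--" if edge["inhibitory"] else "-"
            arrow = "<->" if edge["reciprocal"] else "->"
            ax.annotate(
                "", xy=(x1, y1), xytext=(x0, y0),
                arrowprops=dict(arrowstyle=arrow, linestyle=style, color="C0"),
            )
        for node in pw.nodes:
            x, y = pos[node]
            cls = pw.node_classes.get(node, "")
            ax.plot(x, y, "o", color="C1", zorder=3)
            label = f"{node} ({cls})" if cls and cls != "unknown" else node
            ax.annotate(label, (x, y), textcoords="offset points",
                        xytext=(0, 7), ha="center", fontsize=8)
    ax.set_yticks([])
    ax.set_xlabel("anterior-posterior soma position")
    ax.set_title("critical synapse pathways")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
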