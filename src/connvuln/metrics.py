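"""Nodal and global measures for weighted directed graphs.

All measures follow the standard weighted-connectome conventions:

* The *distance* along a connection of weight ``w`` is ``1/w``; path
  lengths are sums of these distances, so strong connections are short.
* Global efficiency ``E`` is the mean over ordered node pairs of the
  inverse shortest-path distance (0 for disconnected pairs).
* Betweenness ``B(i)`` and edge betweenness ``EBC`` are unnormalized
  Brandes path counts, with all co-minimal shortest paths counted
  fractionally.  The network summary ``B`` averages ``B(i)`` over *all*
  nodes, including zero-degree nodes.
* The nodal clustering coefficient is the Fagiolo directed-weighted
  triangle formula (weights scaled by the graph maximum and
  cube-rooted); a binary directed variant is selectable.

The heavy lifting (all-pairs Dijkstra, weighted betweenness) is done in
compiled code (scipy / igraph); tests cross-check every measure against
exhaustive enumeration oracles on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .graph import ConnectomeGraph

__all__ = [
    "MetricOptions",
    "GlobalMetrics",
    "edge_distance",
    "distance_matrix",
    "nodal_basic",
    "nodal_clustering",
    "efficiency",
    "nodal_efficiency",
    "betweenness",
    "edge_betweenness",
    "global_metrics",
    "node_metric_table",
    "edge_metric_table",
    "euclidean_edge_lengths",
]


@dataclass(frozen=True)
class MetricOptions:
    """Surfaced formulation choices for the global measures.

    clustering
        ``"fagiolo"`` (directed weighted, default) or ``"binary"``
        (directed unweighted).
    efficiency_direction
        Which direction nodal efficiency averages over: ``"out"``
        (default), ``"in"``, or ``"both"``.  Global ``E`` is unaffected
        (it averages over all ordered pairs either way).
    """

    clustering: str = "fagiolo"
    efficiency_direction: str = "out"

    def __post_init__(self) -> None:
        if self.clustering not in ("fagiolo", "binary"):
            raise ValueError(f"unknown clustering formulation {self.clustering!r}")
        if self.efficiency_direction not in ("out", "in", "both"):
            raise ValueError(
                f"unknown efficiency direction {self.efficiency_direction!r}"
            )


@dataclass(frozen=True)
class GlobalMetrics:
    """The three global summaries: mean clustering, efficiency, mean betweenness."""

    C: float
    E: float
    B: float

    def as_dict(self) -> dict[str, float]:
        return {"C": self.C, "E": self.E, "B": self.B}


def _as_matrix(graph) -> np.ndarray:
    if isinstance(graph, ConnectomeGraph):
        return graph.weight
    return np.asarray(graph, dtype=float)


def edge_distance(weight: float) -> float:
    """Distance of a single connection: the inverse of its weight."""
    if weight <= 0:
        raise ValueError(f"edge weight must be positive, got {weight}")
    return 1.0 / weight


def distance_matrix(graph, scale: float | None = None) -> np.ndarray:
    """All-pairs shortest-path distances under the inverse-weight convention.

    Weights are first normalized by ``scale`` (the graph's maximum
    weight when not given), so single-step distances are ``scale/w``
    and at least 1.  This is a uniform rescaling of the raw ``1/w``
    distances: shortest paths, ties and betweenness counts are
    unchanged, and inverse distances stay within [0, 1].  When a graph
    is an attacked copy, pass the *intact* maximum as ``scale`` so
    efficiencies stay comparable.  Disconnected pairs are ``inf``; the
    diagonal is 0.
    """
    W = _as_matrix(graph)
    if scale is None:
        scale = W.max() if W.size else 1.0
    scale = float(scale) if scale > 0 else 1.0
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, scale / np.where(W > 0, W, 1.0), 0.0)
    return dijkstra(csr_matrix(D), directed=True)


# ----------------------------------------------------------------------
# degree / strength / average weight
# ----------------------------------------------------------------------
def nodal_basic(graph, node: str | None = None):
    """Degree, strength and average-weight families for every node.

    ``D`` counts distinct partners with the direction collapsed (a
    reciprocal pair to one partner counts once), ``D_in``/``D_out``
    count directed connections.  ``Str_x`` sums the corresponding
    weights (``Str = Str_in + Str_out``) and ``AW_x = Str_x / D_x``
    with 0/0 left as NaN (undefined).  Ratios are out/in; 0/0 is NaN.

    Returns a DataFrame indexed by node name, or a single row (Series)
    when ``node`` is given.
    """
    if not isinstance(graph, ConnectomeGraph):
        raise TypeError("nodal_basic requires a ConnectomeGraph")
    W = graph.weight
    A = W > 0
    D_out = A.sum(axis=1).astype(float)
    D_in = A.sum(axis=0).astype(float)
    D = (A | A.T).sum(axis=1).astype(float)
    Str_out = W.sum(axis=1)
    Str_in = W.sum(axis=0)
    Str = Str_in + Str_out
    with np.errstate(divide="ignore", invalid="ignore"):
        AW = np.where(D > 0, Str / np.where(D > 0, D, 1), np.nan)
        AW_in = np.where(D_in > 0, Str_in / np.where(D_in > 0, D_in, 1), np.nan)
        AW_out = np.where(D_out > 0, Str_out / np.where(D_out > 0, D_out, 1), np.nan)
        D_ratio = _ratio(D_out, D_in)
        Str_ratio = _ratio(Str_out, Str_in)
        AW_ratio = _ratio(AW_out, AW_in)
    df = pd.DataFrame(
        {
            "D": D,
            "D_in": D_in,
            "D_out": D_out,
            "Str": Str,
            "Str_in": Str_in,
            "Str_out": Str_out,
            "AW": AW,
            "AW_in": AW_in,
            "AW_out": AW_out,
            "D_ratio": D_ratio,
            "Str_ratio": Str_ratio,
            "AW_ratio": AW_ratio,
        },
        index=pd.Index(graph.nodes, name="neuron"),
    )
    if node is not None:
        graph.index(node)  # raises on unknown node
        return df.loc[node]
    return df


def _ratio(out: np.ndarray, inn: np.ndarray) -> np.ndarray:
    """out/in with 0/0 (and NaN inputs) undefined -> NaN, x/0 -> inf."""
    out = np.asarray(out, dtype=float)
    inn = np.asarray(inn, dtype=float)
    res = np.full(out.shape, np.nan)
    ok = inn > 0
    res[ok] = out[ok] / inn[ok]
    res[(inn == 0) & (out > 0)] = np.inf
    return res


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------
def nodal_clustering(
    graph, node: str | None = None, kind: str = "fagiolo",
    scale: float | None = None,
):
    """Directed clustering coefficient per node, in [0, 1].

    The weighted (Fagiolo) form scales weights by the graph maximum and
    cube-roots them; with ``S = W^(1/3) + (W^T)^(1/3)``,

        C_i = (S^3)_ii / (2 [ d_tot(d_tot - 1) - 2 d_bi ])

    where ``d_tot = d_in + d_out`` and ``d_bi`` counts reciprocal
    partners.  Nodes with fewer than two neighbors have C_i = 0.  The
    binary form uses the adjacency pattern instead of weights.
    """
    W = _as_matrix(graph)
    A = (W > 0).astype(float)
    if kind == "fagiolo":
        wmax = scale if scale is not None else (W.max() if W.size else 1.0)
        S = np.cbrt(W / wmax if wmax > 0 else W)
        S = S + S.T
    elif kind == "binary":
        S = A + A.T
    else:
        raise ValueError(f"unknown clustering formulation {kind!r}")
    triangles = ((S @ S) * S.T).sum(axis=1)  # diag(S^3), via BLAS
    d_tot = A.sum(axis=1) + A.sum(axis=0)
    d_bi = np.einsum("ij,ji->i", A, A)
    denom = 2.0 * (d_tot * (d_tot - 1) - 2.0 * d_bi)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    if node is not None:
        return float(C[graph.index(node)])
    return C


# ----------------------------------------------------------------------
# efficiency
# ----------------------------------------------------------------------
def efficiency(graph, scale: float | None = None) -> float:
    """Global efficiency: mean inverse shortest-path distance over ordered pairs.

    Distances come from :func:`distance_matrix` (max-normalized
    weights), so E lies in [0, 1]; it is 1 exactly when every ordered
    pair is joined by a maximum-weight direct connection.
    """
    W = _as_matrix(graph)
    n = W.shape[0]
    if n < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    D = distance_matrix(W, scale)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(
    graph, node: str | None = None, direction: str = "out",
    scale: float | None = None,
):
    """Nodal efficiency: mean inverse distance between a node and all others.

    ``direction`` selects outgoing distances (default), incoming, or
    the average of both.
    """
    W = _as_matrix(graph)
    n = W.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    D = distance_matrix(W, scale)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    out = inv.sum(axis=1) / (n - 1)
    if direction == "out":
        E_i = out
    elif direction == "in":
        E_i = inv.sum(axis=0) / (n - 1)
    elif direction == "both":
        E_i = (out + inv.sum(axis=0) / (n - 1)) / 2.0
    else:
        raise ValueError(f"unknown efficiency direction {direction!r}")
    if node is not None:
        return float(E_i[graph.index(node)])
    return E_i


# ----------------------------------------------------------------------
# betweenness
# ----------------------------------------------------------------------
def _to_igraph(W: np.ndarray) -> tuple[ig.Graph, list[float], np.ndarray]:
    edges = np.argwhere(W > 0)
    dists = [1.0 / W[i, j] for i, j in edges]
    g = ig.Graph(n=W.shape[0], edges=[tuple(e) for e in edges], directed=True)
    return g, dists, edges


def betweenness(graph, node: str | None = None):
    """Unnormalized weighted betweenness B_i per node (shortest-path counts).

    Returns an array aligned with the node order, or a scalar for one
    node.  All co-minimal paths are counted fractionally.
    """
    W = _as_matrix(graph)
    g, dists, _ = _to_igraph(W)
    B = np.array(g.betweenness(weights=dists or None), dtype=float)
    if node is not None:
        return float(B[graph.index(node)])
    return B


def edge_betweenness(graph) -> dict[tuple[int, int], float]:
    """Weighted edge betweenness centrality keyed by (source, target) index."""
    W = _as_matrix(graph)
    g, dists, edges = _to_igraph(W)
    if len(edges) == 0:
        return {}
    eb = g.edge_betweenness(weights=dists)
    return {(int(i), int(j)): float(b) for (i, j), b in zip(edges, eb)}


# ----------------------------------------------------------------------
# global summary and tables
# ----------------------------------------------------------------------
def global_metrics(
    graph, options: MetricOptions | None = None, scale: float | None = None
) -> GlobalMetrics:
    """The three global summaries (C, E, B) of one graph.

    C is the mean nodal clustering coefficient, E the global
    efficiency, B the mean unnormalized betweenness over all nodes
    (zero-degree nodes contribute 0).  ``scale`` fixes the weight
    normalization (pass the intact maximum when measuring attacked
    copies).  Deterministic for fixed input.
    """
    options = options or MetricOptions()
    W = _as_matrix(graph)
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    C = float(np.mean(nodal_clustering(W, kind=options.clustering, scale=scale)))
    E = efficiency(W, scale) if n >= 2 else 0.0
    B = float(np.mean(betweenness(W)))
    return GlobalMetrics(C=C, E=E, B=B)


def node_metric_table(
    graph: ConnectomeGraph, options: MetricOptions | None = None
) -> pd.DataFrame:
    """All nodal measures (D/Str/AW families, C_i, E_i, B_i) in one table."""
    options = options or MetricOptions()
    df = nodal_basic(graph)
    df["C_i"] = nodal_clustering(graph.weight, kind=options.clustering)
    df["E_i"] = nodal_efficiency(
        graph.weight, direction=options.efficiency_direction
    )
    df["B_i"] = betweenness(graph.weight)
    return df


def edge_metric_table(
    graph: ConnectomeGraph, meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-edge weight, edge betweenness and Euclidean soma distance."""
    W = graph.weight
    ebc = edge_betweenness(W)
    rows = []
    lengths = euclidean_edge_lengths(graph, meta) if meta is not None else None
    for i, j in graph.edge_array():
        u, v = graph.nodes[i], graph.nodes[j]
        rows.append(
            {
                "source": u,
                "target": v,
                "weight": int(W[i, j]),
                "EBC": ebc[(i, j)],
                "euclid_len": lengths.get((u, v), np.nan) if lengths else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["source", "target", "weight", "EBC", "euclid_len"]
    )


def euclidean_edge_lengths(
    graph: ConnectomeGraph, meta: pd.DataFrame
) -> dict[tuple[str, str], float]:
    """Straight-line soma distance for every edge; missing coordinates -> NaN."""
    from .io import soma_positions

    pos = soma_positions(meta)
    out: dict[tuple[str, str], float] = {}
    for i, j in graph.edge_array():
        u, v = graph.nodes[i], graph.nodes[j]
        if u in pos and v in pos:
            out[(u, v)] = float(np.linalg.norm(pos[u] - pos[v]))
        else:
            out[(u, v)] = np.nan
    return out
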