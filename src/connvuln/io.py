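"""Reading, validation and serialization of connectome data.

Edge lists are flat delimited text (comma or tab, auto-detected) with a
header containing ``source``, ``target`` and ``count`` columns.
Chemical rows are directed contact counts; gap-junction rows describe
undirected junctions and are expanded to both ordered pairs on read.

Metadata is a per-neuron CSV with columns ``name``, ``class`` (S/I/M),
``birth_time`` (minutes post-fertilization), ``soma_x`` (optionally
``soma_y``, ``soma_z``), ``lr_partner``, ``functions``
(semicolon-separated labels) and ``inhibitory_targets``
(semicolon-separated target neurons, or ``*`` for all chemical
outputs).

Graphs serialize to GraphML (per-edge chemical and gap weights kept as
attributes) with the metadata as a sidecar CSV, so a round trip is
lossless pair-for-pair and weight-for-weight.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph import ConnectomeGraph

__all__ = [
    "read_edge_list",
    "read_metadata",
    "build_combined_graph",
    "serialize",
    "deserialize",
    "write_edge_lists",
]

_EDGE_COLUMNS = ("source", "target", "count")

META_COLUMNS = (
    "name",
    "class",
    "birth_time",
    "soma_x",
    "soma_y",
    "soma_z",
    "lr_partner",
    "functions",
    "inhibitory_targets",
)


def _sniff_delimiter(path: Path) -> str:
    header = path.read_text().splitlines()
    if not header:
        raise ValueError(f"{path}: empty file")
    return "\t" if "\t" in header[0] else ","


def read_edge_list(path, kind: str) -> pd.DataFrame:
    """Read a chemical or gap-junction edge list.

    Parameters
    ----------
    path
        Delimited text file with header columns source, target, count.
    kind
        ``"chemical"`` (rows are directed) or ``"gap"`` (each row is an
        undirected junction, expanded to both ordered pairs with equal
        count).

    Returns
    -------
    DataFrame with columns source, target, count; one row per ordered
    pair (duplicated pairs are summed).
    """
    if kind not in ("chemical", "gap"):
        raise ValueError(f"kind must be 'chemical' or 'gap', got {kind!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df[list(_EDGE_COLUMNS)].copy()
    for col in ("source", "target"):
        df[col] = df[col].str.strip()

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts <= 0) | (counts != np.floor(counts))
    if bad.any():
        rows = ", ".join(str(i + 2) for i in df.index[bad][:5])  # +2: header+1-based
        raise ValueError(
            f"{path}: non-positive or non-integer count at file line(s) {rows}"
        )
    df["count"] = counts.astype(int)

    selfpairs = df["source"] == df["target"]
    if selfpairs.any():
        offenders = df.loc[selfpairs, "source"].unique().tolist()
        warnings.warn(
            f"{path}: dropping {int(selfpairs.sum())} self-connection row(s) "
            f"({', '.join(offenders[:5])})",
            stacklevel=2,
        )
        df = df[~selfpairs]

    if kind == "gap":
        flipped = df.rename(columns={"source": "target", "target": "source"})
        df = pd.concat([df, flipped[list(_EDGE_COLUMNS)]], ignore_index=True)
    # merge duplicate ordered pairs
    df = (
        df.groupby(["source", "target"], sort=False, as_index=False)["count"].sum()
    )
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read the neuron metadata table, indexed by neuron name."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for required in ("name", "class"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required column {required!r}")
    df["name"] = df["name"].str.strip()
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"{path}: duplicate neuron name(s) {dupes}")
    df = df.set_index("name", drop=False)
    if "birth_time" in df.columns:
        df["birth_time"] = pd.to_numeric(df["birth_time"], errors="coerce")
    for axis in ("soma_x", "soma_y", "soma_z"):
        if axis in df.columns:
            df[axis] = pd.to_numeric(df[axis], errors="coerce")
    _check_partner_symmetry(df)
    return df


def _check_partner_symmetry(meta: pd.DataFrame) -> None:
    if "lr_partner" not in meta.columns:
        return
    partners = meta["lr_partner"].dropna()
    for name, partner in partners.items():
        if not partner or pd.isna(partner):
            continue
        if partner in meta.index:
            back = meta.at[partner, "lr_partner"]
            if pd.isna(back) or back != name:
                raise ValueError(
                    f"asymmetric L/R partnership: {name!r} -> {partner!r} "
                    f"but {partner!r} -> {back!r}"
                )


def soma_positions(meta: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-neuron soma coordinate vectors (1-3 components, NaN-free only)."""
    axes = [a for a in ("soma_x", "soma_y", "soma_z") if a in meta.columns]
    out: dict[str, np.ndarray] = {}
    for name, row in meta.iterrows():
        coords = np.array([row[a] for a in axes], dtype=float)
        if len(coords) and not np.any(np.isnan(coords)):
            out[str(name)] = coords
    return out


def build_combined_graph(
    chem: pd.DataFrame,
    gap: pd.DataFrame,
    roster: list[str] | None = None,
) -> ConnectomeGraph:
    """Combine chemical and gap edge tables into one weighted digraph.

    The weight of an ordered pair is the chemical count plus the gap
    count; provenance is retained per layer.  When a ``roster`` is
    given the node set is exactly that list (isolated roster neurons
    keep zero degree) and edges naming unknown neurons are an error.
    """
    names_in_edges: dict[str, None] = {}
    for table in (chem, gap):
        for col in ("source", "target"):
            for name in table[col]:
                names_in_edges.setdefault(name)
    if roster is None:
        nodes = list(names_in_edges)
    else:
        nodes = list(roster)
        unknown = [n for n in names_in_edges if n not in set(nodes)]
        if unknown:
            raise ValueError(
                f"edge list names not in roster: {sorted(unknown)[:10]}"
                + ("..." if len(unknown) > 10 else "")
            )
    idx = {name: i for i, name in enumerate(nodes)}
    n = len(nodes)
    chem_w = np.zeros((n, n))
    gap_w = np.zeros((n, n))
    for table, layer in ((chem, chem_w), (gap, gap_w)):
        for u, v, w in table[["source", "target", "count"]].itertuples(index=False):
            layer[idx[u], idx[v]] += w
    return ConnectomeGraph(nodes, chem_w, gap_w)


def serialize(graph: ConnectomeGraph, path, meta: pd.DataFrame | None = None) -> None:
    """Write a graph as GraphML; metadata goes to a sidecar ``<path>.meta.csv``."""
    path = Path(path)
    G = nx.DiGraph()
    G.add_nodes_from((name, {"order": i}) for i, name in enumerate(graph.nodes))
    for i, j in zip(*np.nonzero(graph.weight)):
        G.add_edge(
            graph.nodes[i],
            graph.nodes[j],
            chem=int(graph.chem[i, j]),
            gap=int(graph.gap[i, j]),
        )
    nx.write_graphml(G, path)
    if meta is not None:
        meta.to_csv(_meta_sidecar(path), index=False)


def _meta_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.csv")


def deserialize(path) -> tuple[ConnectomeGraph, pd.DataFrame | None]:
    """Read a graph written by :func:`serialize`; lossless round trip."""
    path = Path(path)
    try:
        G = nx.read_graphml(path)
    except Exception as exc:
        raise ValueError(f"{path}: malformed GraphML ({exc})") from exc
    nodes = sorted(G.nodes, key=lambda u: int(G.nodes[u].get("order", 0)))
    idx = {name: i for i, name in enumerate(nodes)}
    n = len(nodes)
    chem = np.zeros((n, n))
    gap = np.zeros((n, n))
    for u, v, data in G.edges(data=True):
        chem[idx[u], idx[v]] = data.get("chem", 0)
        gap[idx[u], idx[v]] = data.get("gap", 0)
    graph = ConnectomeGraph(nodes, chem, gap)
    sidecar = _meta_sidecar(path)
    meta = None
    if sidecar.exists():
        meta = read_metadata(sidecar)
    return graph, meta


def write_edge_lists(graph: ConnectomeGraph, outdir, meta: pd.DataFrame | None = None):
    """Write chemical/gap edge lists (and metadata) in the ingestible format.

    Gap junctions are written once per undirected pair.  Returns the
    paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chem_path = outdir / "chemical.csv"
    gap_path = outdir / "gap.csv"
    with open(chem_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EDGE_COLUMNS)
        for i, j in zip(*np.nonzero(graph.chem)):
            w.writerow([graph.nodes[i], graph.nodes[j], int(graph.chem[i, j])])
    with open(gap_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EDGE_COLUMNS)
        for i, j in zip(*np.nonzero(np.triu(graph.gap))):
            w.writerow([graph.nodes[i], graph.nodes[j], int(graph.gap[i, j])])
    paths = [chem_path, gap_path]
    if meta is not None:
        meta_path = outdir / "metadata.csv"
        meta.to_csv(meta_path, index=False)
        paths.append(meta_path)
    return paths
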