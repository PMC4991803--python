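"""Exhaustive single-node and single-edge attack simulations.

An attack on a neuron deletes every connection incident to it but
keeps the neuron in the adjacency matrix with zero degree, so the node
count never changes.  An attack on a synapse deletes one ordered
weighted connection (both its chemical and gap provenance parts); the
reverse direction, if present, is untouched.

The vulnerability of the network to an attack is the relative change
of a global property X:

    V_x(i) = |X - X(i)| / X

where X is the intact value and X(i) the post-attack value.  The
signed version sV_x = (X - X(i)) / X is kept as well, because its sign
is informative: a negative sV_B means the average betweenness
*increased* when the component was removed (longer detours carrying
more shortest-path traffic), while sV_E is always >= 0 because
removing connections can never shorten a shortest path.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .graph import ConnectomeGraph
from .metrics import GlobalMetrics, MetricOptions, betweenness, efficiency, nodal_clustering

__all__ = [
    "attack_node",
    "attack_edge",
    "vulnerability",
    "run_node_attacks",
    "run_edge_attacks",
]


def attack_node(graph: ConnectomeGraph, node: str) -> ConnectomeGraph:
    """Delete all connections of ``node``; the node stays with zero degree."""
    k = graph.index(node)
    out = graph.copy()
    out.chem[k, :] = 0
    out.chem[:, k] = 0
    out.gap[k, :] = 0
    out.gap[:, k] = 0
    return out


def attack_edge(graph: ConnectomeGraph, source: str, target: str) -> ConnectomeGraph:
    """Delete the single ordered connection source -> target.

    The full combined weight (chemical and gap parts) of that direction
    is removed; the reverse direction is untouched, so the attacked
    graph may have an asymmetric gap layer.
    """
    i, j = graph.index(source), graph.index(target)
    if graph.weight[i, j] <= 0:
        raise KeyError(f"no connection {source!r} -> {target!r}")
    out = graph.copy()
    out.chem[i, j] = 0
    out.gap[i, j] = 0
    return out


def vulnerability(X: float, X_att: float) -> tuple[float, float]:
    """Relative change (absolute, signed) of a property after an attack.

    Returns ``(V, sV)`` with ``sV = (X - X_att) / X`` and ``V = |sV|``.
    When the intact value X is 0 the statistic is undefined and both
    are NaN (flagged missing, never an infinity).
    """
    if X == 0 or not math.isfinite(X):
        return (float("nan"), float("nan"))
    sV = (X - X_att) / X
    return (abs(sV), sV)


def _metric_arrays(
    W: np.ndarray, options: MetricOptions, scale: float
) -> tuple[float, float, float]:
    # attacked copies are measured on the intact weight scale so that
    # efficiencies stay comparable (and sV_E >= 0 is guaranteed)
    C = float(np.mean(nodal_clustering(W, kind=options.clustering, scale=scale)))
    E = efficiency(W, scale)
    B = float(np.mean(betweenness(W)))
    return C, E, B


_RECORD_COLUMNS = [
    "X_C", "X_E", "X_B",
    "V_C", "V_E", "V_B",
    "sV_C", "sV_E", "sV_B",
]


def _record(intact: GlobalMetrics, attacked: tuple[float, float, float]) -> dict:
    row: dict[str, float] = {}
    for name, X, X_att in zip("CEB", (intact.C, intact.E, intact.B), attacked):
        V, sV = vulnerability(X, X_att)
        row[f"X_{name}"] = X_att
        row[f"V_{name}"] = V
        row[f"sV_{name}"] = sV
    return row


def run_node_attacks(
    graph: ConnectomeGraph,
    options: MetricOptions | None = None,
    intact: GlobalMetrics | None = None,
) -> pd.DataFrame:
    """Attack every neuron in turn; one vulnerability record per node.

    Each attack starts from the intact graph, so the records are
    independent and the output does not depend on iteration order.
    """
    from .metrics import global_metrics

    options = options or MetricOptions()
    intact = intact or global_metrics(graph, options)
    W = graph.weight
    scale = float(W.max()) if W.size and W.max() > 0 else 1.0
    rows = []
    for k, name in enumerate(graph.nodes):
        Wk = W.copy()
        Wk[k, :] = 0
        Wk[:, k] = 0
        rows.append(
            {"target": name, **_record(intact, _metric_arrays(Wk, options, scale))}
        )
    df = pd.DataFrame(rows, columns=["target"] + _RECORD_COLUMNS)
    return df.set_index("target")


def run_edge_attacks(
    graph: ConnectomeGraph,
    options: MetricOptions | None = None,
    intact: GlobalMetrics | None = None,
) -> pd.DataFrame:
    """Attack every ordered weighted connection in turn, one record each."""
    from .metrics import global_metrics

    options = options or MetricOptions()
    intact = intact or global_metrics(graph, options)
    W = graph.weight
    scale = float(W.max()) if W.size and W.max() > 0 else 1.0
    rows = []
    for i, j in graph.edge_array():
        Wk = W.copy()
        Wk[i, j] = 0
        rows.append(
            {
                "source": graph.nodes[i],
                "target": graph.nodes[j],
                **_record(intact, _metric_arrays(Wk, options, scale)),
            }
        )
    df = pd.DataFrame(rows, columns=["source", "target"] + _RECORD_COLUMNS)
    return df.set_index(["source", "target"])
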