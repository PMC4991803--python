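"""Structural robustness summaries: leaves, isolation, reachability.

These complement the attack sweep with coarser topological checks:
which neurons hang off the network by a single partner, how much of
the network is stranded when one neuron is deleted, and which ordered
pairs can communicate at all through each provenance layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .attack import attack_node
from .graph import ConnectomeGraph

__all__ = [
    "find_leaves",
    "isolation_after_attack",
    "ReachabilityMatrix",
    "reachability_matrix",
    "reachability_coding",
]


def find_leaves(graph: ConnectomeGraph) -> list[str]:
    """Neurons with exactly one connection partner (direction-collapsed)."""
    A = graph.weight > 0
    partners = (A | A.T).sum(axis=1)
    return [name for name, k in zip(graph.nodes, partners) if k == 1]


def isolation_after_attack(graph: ConnectomeGraph, node: str) -> dict:
    """Isolation produced by one neuronal attack.

    Reports the number and fraction of zero-degree nodes in the
    attacked network plus the weakly connected component size
    distribution (largest first), covering both stranded individual
    neurons and stranded subnetworks.
    """
    attacked = attack_node(graph, node)
    A = attacked.weight > 0
    degree = (A | A.T).sum(axis=1)
    isolated = [name for name, k in zip(attacked.nodes, degree) if k == 0]
    n_comp, labels = connected_components(
        csr_matrix(A), directed=True, connection="weak"
    )
    sizes = sorted(np.bincount(labels).tolist(), reverse=True)
    return {
        "attacked": node,
        "n_isolated": len(isolated),
        "isolated_fraction": len(isolated) / graph.n_nodes,
        "isolated_nodes": isolated,
        "component_sizes": sizes,
    }


@dataclass
class ReachabilityMatrix:
    """Boolean directed-path reachability over one provenance layer."""

    nodes: list[str]
    reachable: np.ndarray  # (n, n) bool; diagonal True by convention
    network_type: str


def reachability_matrix(
    graph: ConnectomeGraph, network_type: str = "combined"
) -> ReachabilityMatrix:
    """Transitive closure of one layer: gap, chemical or combined.

    The gap layer is symmetric, so its reachability is too; the
    combined closure is always a superset of each single layer.
    """
    W = graph.layer(
        {"gap": "gap", "chemical": "chemical", "combined": "combined"}[network_type]
        if network_type in ("gap", "chemical", "combined")
        else network_type  # raises in layer()
    )
    D = shortest_path(csr_matrix(W > 0), directed=True, unweighted=True)
    reach = np.isfinite(D)
    np.fill_diagonal(reach, True)
    return ReachabilityMatrix(
        nodes=list(graph.nodes), reachable=reach, network_type=network_type
    )


def reachability_coding(graph: ConnectomeGraph) -> np.ndarray:
    """Three-level coded reachability matrix across layers.

    0 = unreachable even in the combined network, 1 = reachable in the
    combined network only (neither single layer suffices), 2 =
    reachable through at least one single layer.
    """
    combined = reachability_matrix(graph, "combined").reachable
    chem = reachability_matrix(graph, "chemical").reachable
    gap = reachability_matrix(graph, "gap").reachable
    coded = np.zeros(combined.shape, dtype=int)
    coded[combined & ~(chem | gap)] = 1
    coded[chem | gap] = 2
    return coded
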