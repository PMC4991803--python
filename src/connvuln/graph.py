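"""Core container for a weighted directed connectome.

A connectome is held as two dense non-negative integer-valued weight
matrices over a fixed, ordered neuron roster: a *chemical* layer
(directed synapse contact counts) and a *gap-junction* layer (electrical
couplings, symmetric by construction).  The combined weight of an
ordered pair is the sum of the two layers; pairs with zero combined
weight are absent connections.

Attacks relax invariants deliberately: removing a single directed pair
of a gap-derived connection leaves the reverse direction in place, so
attacked graphs are built with ``validate=False``.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["ConnectomeGraph"]


class ConnectomeGraph:
    """Weighted directed graph over a fixed neuron roster.

    Parameters
    ----------
    nodes
        Ordered, unique neuron names.  Attacks never change the roster.
    chem, gap
        ``(n, n)`` arrays of non-negative integer contact counts.
        ``chem[i, j]`` counts chemical contacts from neuron ``i`` to
        neuron ``j``; ``gap`` must be symmetric (each undirected
        junction contributes to both ordered pairs).  Diagonals must be
        zero.
    validate
        Check the invariants (symmetric gap layer, zero diagonal,
        non-negative integer weights).  Attacked copies disable this
        because a single-direction removal breaks gap symmetry by
        design.
    """

    __slots__ = ("nodes", "chem", "gap", "_index")

    def __init__(
        self,
        nodes: Sequence[str],
        chem: np.ndarray,
        gap: np.ndarray,
        *,
        validate: bool = True,
    ) -> None:
        self.nodes: list[str] = list(map(str, nodes))
        n = len(self.nodes)
        self.chem = np.asarray(chem, dtype=float)
        self.gap = np.asarray(gap, dtype=float)
        if self.chem.shape != (n, n) or self.gap.shape != (n, n):
            raise ValueError(
                f"weight matrices must be ({n}, {n}); got "
                f"{self.chem.shape} and {self.gap.shape}"
            )
        self._index = {name: i for i, name in enumerate(self.nodes)}
        if len(self._index) != n:
            raise ValueError("duplicate neuron names in roster")
        if validate:
            self._validate()

    def _validate(self) -> None:
        for name, layer in (("chem", self.chem), ("gap", self.gap)):
            if np.any(layer < 0):
                raise ValueError(f"negative weights in {name} layer")
            if np.any(layer != np.round(layer)):
                raise ValueError(f"non-integer contact counts in {name} layer")
            if np.any(np.diag(layer) != 0):
                raise ValueError(f"self-connections present in {name} layer")
        if not np.array_equal(self.gap, self.gap.T):
            raise ValueError("gap-junction layer is not symmetric")

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def weight(self) -> np.ndarray:
        """Combined ``(n, n)`` weight matrix (chemical + gap)."""
        return self.chem + self.gap

    @property
    def n_edges(self) -> int:
        """Number of ordered pairs with positive combined weight."""
        return int(np.count_nonzero(self.weight))

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown neuron {node!r}") from None

    def __contains__(self, node: object) -> bool:
        return node in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConnectomeGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and np.array_equal(self.chem, other.chem)
            and np.array_equal(self.gap, other.gap)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ConnectomeGraph n_nodes={self.n_nodes} n_edges={self.n_edges} "
            f"chem={int(self.chem.sum())} gap={int(self.gap.sum())}>"
        )

    def edges(self) -> Iterator[tuple[str, str, int]]:
        """Yield ``(source, target, combined_weight)`` for every stored pair."""
        W = self.weight
        for i, j in zip(*np.nonzero(W)):
            yield self.nodes[i], self.nodes[j], int(W[i, j])

    def edge_array(self) -> np.ndarray:
        """``(m, 2)`` integer array of (source, target) indices, row-major order."""
        return np.argwhere(self.weight > 0)

    def copy(self, *, validate: bool = False) -> "ConnectomeGraph":
        return ConnectomeGraph(
            self.nodes, self.chem.copy(), self.gap.copy(), validate=validate
        )

    # ------------------------------------------------------------------
    # layer selection
    # ------------------------------------------------------------------
    def layer(self, which: str = "combined") -> np.ndarray:
        """Weight matrix of a provenance layer: chemical, gap or combined."""
        if which == "combined":
            return self.weight
        if which == "chemical":
            return self.chem.copy()
        if which == "gap":
            return self.gap.copy()
        raise ValueError(
            f"unknown layer {which!r}; expected chemical, gap or combined"
        )

    # ------------------------------------------------------------------
    # conversions
    # ------------------------------------------------------------------
    def to_networkx(self):
        """Combined graph as a :class:`networkx.DiGraph` with weight attributes."""
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.nodes)
        W = self.weight
        for i, j in zip(*np.nonzero(W)):
            G.add_edge(
                self.nodes[i],
                self.nodes[j],
                weight=int(W[i, j]),
                chem=int(self.chem[i, j]),
                gap=int(self.gap[i, j]),
            )
        return G

    @classmethod
    def from_weight_matrices(
        cls,
        nodes: Sequence[str],
        chem: np.ndarray,
        gap: np.ndarray | None = None,
        **kwargs,
    ) -> "ConnectomeGraph":
        n = len(nodes)
        if gap is None:
            gap = np.zeros((n, n))
        return cls(nodes, chem, gap, **kwargs)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        nodes: Sequence[str] | None = None,
        *,
        drop_self_loops: bool = True,
    ) -> "ConnectomeGraph":
        """Build a chemical-only graph from ``(source, target, count)`` triples.

        Convenience constructor for tests and synthetic inputs; file
        ingestion with provenance goes through :mod:`connvuln.io`.
        """
        edges = list(edges)
        if nodes is None:
            seen: dict[str, None] = {}
            for u, v, _ in edges:
                seen.setdefault(u)
                seen.setdefault(v)
            nodes = list(seen)
        idx = {name: i for i, name in enumerate(nodes)}
        n = len(nodes)
        chem = np.zeros((n, n))
        for u, v, w in edges:
            if u == v:
                if drop_self_loops:
                    warnings.warn(f"dropping self-connection {u!r}", stacklevel=2)
                    continue
                raise ValueError(f"self-connection {u!r}")
            chem[idx[u], idx[v]] += w
        return cls(nodes, chem, np.zeros((n, n)))
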