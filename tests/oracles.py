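"""Brute-force enumeration oracles for small weighted digraphs.

Deliberately independent of the package implementation: shortest paths
are enumerated as simple paths with lengths accumulated in exact
rational arithmetic (``fractions.Fraction``), so tied co-minimal paths
are detected without any floating-point ambiguity, and the clustering
oracle evaluates the directed-weighted triangle formula by explicit
triple loop.  Only usable for graphs of ~7 nodes.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def _all_shortest_paths(W: np.ndarray, scale: int):
    """For every ordered pair: (min rational distance, list of min paths)."""
    n = W.shape[0]
    result: dict[tuple[int, int], tuple[Fraction, list[list[int]]]] = {}
    for s, t in itertools.permutations(range(n), 2):
        paths = []
        stack = [(s, [s], Fraction(0))]
        while stack:
            u, path, d = stack.pop()
            if u == t:
                paths.append((d, path))
                continue
            for v in range(n):
                if W[u, v] > 0 and v not in path:
                    stack.append((v, path + [v], d + Fraction(scale, int(W[u, v]))))
        if not paths:
            continue
        dmin = min(d for d, _ in paths)
        result[(s, t)] = (dmin, [p for d, p in paths if d == dmin])
    return result


def betweenness_oracle(W: np.ndarray):
    """(B_i array, EBC dict keyed by index pair) by exhaustive path counting."""
    n = W.shape[0]
    B = np.zeros(n)
    EB = {(i, j): 0.0 for i, j in zip(*np.nonzero(W))}
    for (s, t), (_, paths) in _all_shortest_paths(W, 1).items():
        sigma = len(paths)
        for p in paths:
            for v in p[1:-1]:
                B[v] += 1.0 / sigma
            for a, b in zip(p, p[1:]):
                EB[(a, b)] += 1.0 / sigma
    return B, EB


def efficiency_oracle(W: np.ndarray) -> float:
    """Mean inverse shortest-path distance on the max-normalized scale."""
    n = W.shape[0]
    scale = int(W.max()) if W.max() > 0 else 1
    sp = _all_shortest_paths(W, scale)
    total = sum(Fraction(1) / d for d, _ in sp.values())
    return float(total / (n * (n - 1)))


def nodal_efficiency_oracle(W: np.ndarray, direction: str = "out") -> np.ndarray:
    n = W.shape[0]
    scale = int(W.max()) if W.max() > 0 else 1
    sp = _all_shortest_paths(W, scale)
    E = np.zeros(n)
    for (s, t), (d, _) in sp.items():
        inv = float(Fraction(1) / d)
        if direction == "out":
            E[s] += inv
        elif direction == "in":
            E[t] += inv
        else:
            E[s] += inv / 2.0
            E[t] += inv / 2.0
    return E / (n - 1)


def clustering_oracle(W: np.ndarray) -> np.ndarray:
    """Directed-weighted clustering by explicit triple loop."""
    n = W.shape[0]
    wmax = W.max() if W.max() > 0 else 1.0
    Wh = np.cbrt(W / wmax)
    A = (W > 0).astype(int)
    C = np.zeros(n)
    for i in range(n):
        tri = 0.0
        for j in range(n):
            for k in range(n):
                tri += (
                    (Wh[i, j] + Wh[j, i])
                    * (Wh[j, k] + Wh[k, j])
                    * (Wh[k, i] + Wh[i, k])
                )
        d_tot = A[i, :].sum() + A[:, i].sum()
        d_bi = int((A[i, :] * A[:, i]).sum())
        denom = 2.0 * (d_tot * (d_tot - 1) - 2 * d_bi)
        C[i] = tri / denom if denom > 0 else 0.0
    return C


def random_small_graph(rng: np.random.Generator, max_n: int = 7) -> np.ndarray:
    """Random integer-weight digraph with 3..max_n nodes, density ~0.4."""
    n = int(rng.integers(3, max_n + 1))
    W = np.where(
        rng.random((n, n)) < 0.4, rng.integers(1, 10, (n, n)), 0
    ).astype(float)
    np.fill_diagonal(W, 0)
    return W
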