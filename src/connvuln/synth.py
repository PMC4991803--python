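"""Synthetic connectome generator with planted, known structure.

Emulates the statistical shape of the *C. elegans* hermaphrodite
wiring data so every pipeline stage can be exercised without the
published tables: ~279 neurons in three classes (sensory, inter,
motor), a hub-skewed in/out degree distribution with interneurons
biased toward hubhood, positive integer contact-count weights, a
symmetric gap-junction layer carrying a minority of the weight,
left/right paired names, class-dependent birth times and 1-D soma
positions on the anterior-posterior axis.

Structures can be *planted* with a key recording exactly what was
planted, so recovery by the attack/criticality pipeline is checkable:

* ``hub`` -- a node wired up to the top of the degree distribution;
* ``reciprocal_strong_pair`` -- two neurons with mutual weights an
  order of magnitude above the median (mimicking AVAL <-> AVAR);
* ``bridge_edge`` -- the sole connection between two otherwise
  internally dense blocks (a maximally central edge);
* ``chain`` -- a directed path of strongly weighted links acting as a
  shortest-path superhighway.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph import ConnectomeGraph

__all__ = ["SynthSpec", "generate_connectome", "plant_structures"]

_EARLY = (250.0, 470.0)  # minutes post-fertilization, before first twitch
_LATE = (800.0, 1500.0)
_P_EARLY = {"S": 0.6, "I": 0.9, "M": 0.5}
_CLASS_PREFIX = {"S": "SE", "I": "IN", "M": "MO"}

_FUNCTION_POOLS = {
    "S": ["chemosensation", "aerotaxis", "touch response", "mechanosensation"],
    "I": [
        "locomotion",
        "information integration",
        "chemotaxis",
        "ventral cord pioneering",
    ],
    "M": ["locomotion", "sinusoidal body movement", "backward locomotion"],
}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic connectome draw.

    Defaults mirror the published hermaphrodite network scale: 88
    sensory, 82 inter- and 109 motor neurons (279 total), about 2,990
    ordered weighted connections, geometric contact counts with mean
    ~2.4, and ~12% of total weight in the symmetric gap layer.
    """

    n_sensory: int = 88
    n_inter: int = 82
    n_motor: int = 109
    n_edges: int = 2990
    paired_fraction: float = 0.7
    weight_law: str = "geometric"
    weight_p: float = 0.41  # geometric success prob.; mean weight = 1/p
    gap_fraction: float = 0.12
    hub_skew: float = 1.5  # Pareto tail index of degree propensities
    planted: tuple = field(default_factory=tuple)
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return self.n_sensory + self.n_inter + self.n_motor

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 neurons")
        if min(self.n_sensory, self.n_inter, self.n_motor) < 0:
            raise ValueError("class sizes must be non-negative")
        if not 0 <= self.gap_fraction <= 1:
            raise ValueError("gap_fraction must lie in [0, 1]")
        if not 0 <= self.paired_fraction <= 1:
            raise ValueError("paired_fraction must lie in [0, 1]")
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError(
                f"{self.n_edges} edges infeasible for {self.n_nodes} nodes"
            )
        if self.weight_law not in ("geometric", "zipf"):
            raise ValueError(f"unknown weight law {self.weight_law!r}")


def _draw_weights(rng: np.random.Generator, spec: SynthSpec, size: int) -> np.ndarray:
    if spec.weight_law == "geometric":
        return rng.geometric(spec.weight_p, size=size)
    return rng.zipf(1.0 + 1.0 / spec.weight_p, size=size)


def _names_and_meta(rng: np.random.Generator, spec: SynthSpec):
    names: list[str] = []
    rows: list[dict] = []
    for cls, count in (("S", spec.n_sensory), ("I", spec.n_inter), ("M", spec.n_motor)):
        n_pairs = int(round(count * spec.paired_fraction / 2))
        n_single = count - 2 * n_pairs
        prefix = _CLASS_PREFIX[cls]
        stems = [f"{prefix}{i + 1:02d}" for i in range(n_pairs + n_single)]
        members: list[tuple[str, str | None]] = []
        for stem in stems[:n_pairs]:
            members.append((stem + "L", stem + "R"))
            members.append((stem + "R", stem + "L"))
        for stem in stems[n_pairs:]:
            members.append((stem, None))
        pair_pos: dict[str, float] = {}
        for name, partner in members:
            early = rng.random() < _P_EARLY[cls]
            birth = rng.uniform(*(_EARLY if early else _LATE))
            stem = name[:-1] if partner else name
            if stem not in pair_pos:
                pair_pos[stem] = float(rng.random())
            labels = rng.choice(
                _FUNCTION_POOLS[cls],
                size=rng.integers(0, 3),
                replace=False,
            )
            inhibitory = "*" if cls == "M" and rng.random() < 0.15 else ""
            names.append(name)
            rows.append(
                {
                    "name": name,
                    "class": cls,
                    "birth_time": round(birth, 1),
                    "soma_x": round(pair_pos[stem], 4),
                    "lr_partner": partner or "",
                    "functions": ";".join(labels),
                    "inhibitory_targets": inhibitory,
                }
            )
    meta = pd.DataFrame(rows).set_index("name", drop=False)
    return names, meta


def generate_connectome(spec: SynthSpec):
    """Draw one synthetic connectome.

    Returns ``(graph, meta, key)`` where ``key`` records the planted
    structures.  Identical specs (including seed) give bit-identical
    output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names, meta = _names_and_meta(rng, spec)
    n = spec.n_nodes

    # hub-skewed degree propensities; interneurons biased toward hubhood
    prop_out = 1.0 + rng.pareto(spec.hub_skew, n)
    prop_in = 1.0 + rng.pareto(spec.hub_skew, n)
    is_inter = (meta["class"] == "I").to_numpy()
    prop_out[is_inter] *= 2.0
    prop_in[is_inter] *= 2.0

    P = np.outer(prop_out, prop_in)
    np.fill_diagonal(P, 0.0)
    flat = P.ravel() / P.sum()
    chosen = rng.choice(n * n, size=spec.n_edges, replace=False, p=flat)
    chem = np.zeros((n, n))
    weights = _draw_weights(rng, spec, spec.n_edges)
    chem[np.unravel_index(chosen, (n, n))] = weights

    # symmetric gap layer: unordered pairs drawn until the weight budget
    # (gap_fraction of total contacts) is met
    gap = np.zeros((n, n))
    chem_total = chem.sum()
    if spec.gap_fraction > 0 and chem_total > 0:
        budget = spec.gap_fraction / (1.0 - spec.gap_fraction) * chem_total
        sym_prop = prop_out + prop_in
        pair_p = np.triu(np.outer(sym_prop, sym_prop), k=1)
        # electrical couplings preferentially join neurons that already
        # share a chemical contact, so the combined ordered-pair count
        # stays close to the requested n_edges
        connected = (chem > 0) | (chem.T > 0)
        pair_p *= 1.0 + 9.0 * connected
        pair_p = pair_p.ravel() / pair_p.sum()
        n_pairs = n * (n - 1) // 2
        order = rng.choice(n * n, size=min(n_pairs, 4 * spec.n_edges),
                           replace=False, p=pair_p)
        total = 0.0
        for flat_idx in order:
            if total >= budget / 2.0:  # each junction contributes twice
                break
            i, j = np.unravel_index(flat_idx, (n, n))
            w = float(_draw_weights(rng, spec, 1)[0])
            gap[i, j] += w
            gap[j, i] += w
            total += w

    graph = ConnectomeGraph(names, chem, gap)
    key: dict = {}
    if spec.planted:
        graph, key = plant_structures(graph, list(spec.planted), rng=rng)
    return graph, meta, key


def _median_weight(graph: ConnectomeGraph) -> float:
    W = graph.weight
    vals = W[W > 0]
    return float(np.median(vals)) if vals.size else 1.0


def plant_structures(graph: ConnectomeGraph, planted: list[dict], rng=None):
    """Overlay planted structures on a generated graph.

    Each entry is a dict with a ``kind`` key (``hub``,
    ``reciprocal_strong_pair``, ``bridge_edge`` or ``chain``) plus
    optional parameters.  Planting the same node or edge twice is an
    error.  Returns ``(modified graph, key)`` with the key listing
    exactly what was planted where.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    g = graph.copy()
    n = g.n_nodes
    key: dict[str, list] = {}
    used_nodes: set[int] = set()

    def claim(indices) -> None:
        overlap = used_nodes.intersection(indices)
        if overlap:
            raise ValueError(
                "conflicting planted structures on node(s) "
                + ", ".join(g.nodes[i] for i in sorted(overlap))
            )
        used_nodes.update(indices)

    med = _median_weight(g)
    for item in planted:
        kind = item["kind"] if isinstance(item, dict) else str(item)
        params = item if isinstance(item, dict) else {}
        if kind == "hub":
            k = g.index(params["node"]) if "node" in params else int(
                rng.integers(0, n)
            )
            claim([k])
            A = g.weight > 0
            partner_deg = (A | A.T).sum(axis=1)
            target = int(np.max(partner_deg)) + max(2, n // 20)
            target = min(target, n - 1)
            others = [i for i in range(n) if i != k]
            rng.shuffle(others)
            for other in others:
                A = g.weight > 0
                if ((A | A.T).sum(axis=1))[k] >= target:
                    break
                if not (A[k, other] or A[other, k]):
                    if rng.random() < 0.5:
                        g.chem[k, other] += 1
                    else:
                        g.chem[other, k] += 1
            key.setdefault("hub", []).append(g.nodes[k])
        elif kind == "reciprocal_strong_pair":
            if "nodes" in params:
                i, j = (g.index(v) for v in params["nodes"])
            else:
                i, j = rng.choice(n, size=2, replace=False)
            claim([i, j])
            w = int(params.get("weight", np.ceil(10 * med)))
            g.chem[i, j] = w
            g.chem[j, i] = w
            key.setdefault("reciprocal_strong_pair", []).append(
                (g.nodes[i], g.nodes[j])
            )
        elif kind == "bridge_edge":
            frac = float(params.get("block_fraction", 0.5))
            split = int(round(n * frac))
            if split < 2 or n - split < 2:
                raise ValueError("bridge blocks need at least 2 nodes each")
            block_a = np.arange(split)
            block_b = np.arange(split, n)
            # sever every cross-block connection, then lay the single bridge
            g.chem[np.ix_(block_a, block_b)] = 0
            g.chem[np.ix_(block_b, block_a)] = 0
            g.gap[np.ix_(block_a, block_b)] = 0
            g.gap[np.ix_(block_b, block_a)] = 0
            # default endpoints are block hubs (max in-degree feeder in A,
            # max out-degree distributor in B) so the bridge concentrates
            # the entire cross-block traffic on itself rather than on a
            # low-degree endpoint's single continuation edge
            A_att = g.weight > 0
            u = int(params.get(
                "source_index", block_a[np.argmax(A_att[:, block_a].sum(axis=0))]
            ))
            v = int(params.get(
                "target_index", block_b[np.argmax(A_att[block_b, :].sum(axis=1))]
            ))
            claim([u, v])
            g.chem[u, v] = int(params.get("weight", max(1, round(med))))
            key.setdefault("bridge_edge", []).append((g.nodes[u], g.nodes[v]))
            key["bridge_blocks"] = [
                [g.nodes[i] for i in block_a],
                [g.nodes[i] for i in block_b],
            ]
        elif kind == "chain":
            length = int(params.get("length", 4))
            if not 3 <= length <= 5:
                raise ValueError("chain length must be 3-5")
            if "nodes" in params:
                idx = [g.index(v) for v in params["nodes"]]
            else:
                idx = list(rng.choice(n, size=length, replace=False))
            claim(idx)
            w = int(params.get("weight", np.ceil(20 * med)))
            for a, b in zip(idx, idx[1:]):
                g.chem[a, b] = w
            key.setdefault("chain", []).append([g.nodes[i] for i in idx])
        else:
            raise ValueError(f"unknown planted structure kind {kind!r}")
    return g, key


def bridge_recovery_spec(seed: int, n_block: int = 15) -> SynthSpec:
    """Small two-block spec with one planted bridge, used for recovery studies.

    Density is high (half of all ordered pairs before the cross-block
    cut) so each block is internally robust, and weights are drawn
    nearly uniform (geometric with mean ~1.3) so the planted bridge is
    the one structural anomaly rather than competing with heavy-tailed
    weight outliers.
    """
    n = 2 * n_block
    return SynthSpec(
        n_sensory=n_block // 2,
        n_inter=n - n_block,
        n_motor=n_block - n_block // 2,
        n_edges=int(round(0.50 * n * (n - 1))),
        paired_fraction=0.5,
        weight_p=0.75,
        gap_fraction=0.10,
        planted=({"kind": "bridge_edge"},),
        seed=seed,
    )
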