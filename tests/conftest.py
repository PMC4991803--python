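import numpy as np
import pandas as pd
import pytest

from connvuln.graph import ConnectomeGraph


@pytest.fixture
def path_graph() -> ConnectomeGraph:
    """a -> b -> c with unit weights."""
    return ConnectomeGraph.from_edges([("a", "b", 1), ("b", "c", 1)],
                                      nodes=["a", "b", "c"])


@pytest.fixture
def reciprocal_triangle() -> ConnectomeGraph:
    """Complete reciprocal triangle with unit weights."""
    edges = [(u, v, 1) for u in "abc" for v in "abc" if u != v]
    return ConnectomeGraph.from_edges(edges, nodes=list("abc"))


@pytest.fixture
def star5() -> ConnectomeGraph:
    """Hub h connected reciprocally to 4 leaves."""
    edges = []
    for leaf in ["p", "q", "r", "s"]:
        edges += [("h", leaf, 1), (leaf, "h", 1)]
    return ConnectomeGraph.from_edges(edges, nodes=["h", "p", "q", "r", "s"])


@pytest.fixture
def small_meta() -> pd.DataFrame:
    rows = [
        ("AVAL", "I", 312, 0.1, "AVAR", "backward locomotion", ""),
        ("AVAR", "I", 311, 0.1, "AVAL", "backward locomotion", ""),
        ("PVCL", "I", 449, 0.8, "PVCR", "forward locomotion", ""),
        ("PVCR", "I", 450, 0.8, "PVCL", "forward locomotion", ""),
        ("DVC", "I", 351, 0.9, "", "", ""),
        ("VD01", "M", 1460, 0.3, "", "sinusoidal body movement", "*"),
    ]
    df = pd.DataFrame(
        rows,
        columns=["name", "class", "birth_time", "soma_x", "lr_partner",
                 "functions", "inhibitory_targets"],
    )
    return df.set_index("name", drop=False)


def graph_from_matrix(W, gap=None, names=None) -> ConnectomeGraph:
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    names = names or [f"n{i}" for i in range(n)]
    gap = np.zeros((n, n)) if gap is None else np.asarray(gap, dtype=float)
    return ConnectomeGraph(names, W, gap)
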