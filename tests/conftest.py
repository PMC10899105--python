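import numpy as np
import pandas as pd
import pytest

from minipath import BipartiteGraph, UEITable


@pytest.fixture
def k22() -> BipartiteGraph:
    """Complete bipartite 2x2 graph with unit weights."""
    return BipartiteGraph.from_edges([
        ("u1", "v1", 1), ("u1", "v2", 1), ("u2", "v1", 1), ("u2", "v2", 1)])


@pytest.fixture
def path_graph() -> BipartiteGraph:
    """Path u1 - v1 - u2 with unit weights."""
    return BipartiteGraph.from_edges([("u1", "v1", 1), ("u2", "v1", 1)])


def make_uei_table(rows):
    return UEITable(pd.DataFrame(
        rows, columns=["beacon_id", "target_id", "uei_id", "read_count"]))


@pytest.fixture
def uei_rows():
    return [
        ("b1", "t1", "x1", 5),
        ("b1", "t1", "x2", 1),
        ("b1", "t1", "x3", 2),
        ("b1", "t2", "x4", 3),
        ("b2", "t1", "x5", 4),
    ]


def random_bipartite(rng: np.random.Generator, n_u: int, n_v: int,
                     density: float = 0.5, max_w: int = 5) -> BipartiteGraph:
    """Random weighted bipartite graph for oracle comparisons."""
    mask = rng.random((n_u, n_v)) < density
    w = rng.integers(1, max_w + 1, size=(n_u, n_v)) * mask
    u_ids = [f"u{i:03d}" for i in range(n_u)]
    v_ids = [f"v{j:03d}" for j in range(n_v)]
    return BipartiteGraph(u_ids, v_ids, w)
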