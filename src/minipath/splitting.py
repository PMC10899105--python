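"""Fused-node detection by normalized-cut partitioning of neighbor subgraphs.

The neighbors of a normal polony are themselves close together, so they form
one well-connected subgraph under two-step connectivity.  A fused node
inherits the neighbors of two distant polonies, so its neighbor subgraph
separates into two groups with few connections between them.

For a center node ``a`` the neighbor graph G_a has nodes S_a (the neighbors
of ``a``) and, for x, y in S_a, edge weights equal to the weighted two-step
paths that avoid ``a``:

    w_i2(x, y) = sum over b != a of w(b, x) * w(b, y)

(b runs over a's own side of the bipartition).  G_a is partitioned in two and
scored with the Shi–Malik normalized cut

    ncut(S1, S2) = cut(S1, S2) / assoc(S1) + cut(S1, S2) / assoc(S2),

assoc(Si) = sum of w_i2(u, t) over u in Si, t in S_a (ordered pairs, so
within-part weights count once per endpoint).  Nodes with ncut below a cutoff
are split into two nodes inheriting the edges to either part.

Evaluation rules: centers with fewer than ``min_degree`` neighbors are not
considered; a neighbor graph in exactly two connected components is that
bipartition with ncut 0.0; more than two components marks the node
unevaluable (too sparse to judge); otherwise the minimum-ncut bipartition is
found exactly (exhaustive search) for small S_a and by a Fiedler-vector sweep
cut above that size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import BipartiteGraph

__all__ = [
    "NeighborGraph",
    "NodeCut",
    "NodeCutTable",
    "neighbor_graph",
    "ncut_value",
    "evaluate_node",
    "evaluate_all_nodes",
    "split_nodes",
]

Status = Literal["evaluated", "too_few_neighbors", "unevaluable_components"]

#: Largest |S_a| for which the minimum-ncut bipartition is found exhaustively.
EXACT_SEARCH_MAX = 12


@dataclass
class NeighborGraph:
    """Two-step neighbor subgraph of one center node.

    ``w`` is the dense symmetric w_i2 matrix over ``nodes`` with the diagonal
    zeroed (self two-step returns carry no partition information).
    """

    center: str
    nodes: list[str]
    w: np.ndarray

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class NodeCut:
    """Per-node partition result."""

    node: str
    status: Status
    ncut: float | None = None
    part1: list[str] | None = None
    part2: list[str] | None = None


class NodeCutTable(dict):
    """Mapping node id -> :class:`NodeCut` with tabular export."""

    def evaluated(self) -> dict[str, NodeCut]:
        return {k: v for k, v in self.items() if v.status == "evaluated"}

    def ncut_values(self) -> dict[str, float]:
        return {k: v.ncut for k, v in self.evaluated().items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"node_id": c.node, "status": c.status,
                 "ncut": np.nan if c.ncut is None else c.ncut,
                 "partition_1": ",".join(c.part1) if c.part1 else "",
                 "partition_2": ",".join(c.part2) if c.part2 else ""}
                for c in self.values()]
        return pd.DataFrame(rows, columns=["node_id", "status", "ncut",
                                           "partition_1", "partition_2"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Neighbor-graph construction
# ---------------------------------------------------------------------------

def neighbor_graph(g: BipartiteGraph, a: str) -> NeighborGraph:
    """Build G_a for center ``a``: S_a and the w_i2 two-step weights."""
    if a in g.u_index:
        row = g.matrix.getrow(g.u_index[a])
        s_idx = row.indices
        nodes = [g.v_ids[j] for j in s_idx]
        sub = g.matrix[:, s_idx]                      # all U rows, S_a cols
        w_a = row.data.astype(np.float64)
        gram = (sub.T @ sub).toarray().astype(np.float64)
    elif a in g.v_index:
        col = g.matrix.getcol(g.v_index[a]).tocoo()
        s_idx = col.row
        nodes = [g.u_ids[i] for i in s_idx]
        sub = g.matrix[s_idx, :]                      # S_a rows, all V cols
        w_a = col.data.astype(np.float64)
        gram = (sub @ sub.T).toarray().astype(np.float64)
    else:
        raise KeyError(a)
    w = gram - np.outer(w_a, w_a)                     # drop paths through a
    np.fill_diagonal(w, 0.0)
    return NeighborGraph(center=a, nodes=nodes, w=w)


# ---------------------------------------------------------------------------
# Normalized cut
# ---------------------------------------------------------------------------

def _dense_components(w: np.ndarray, max_label: int = 3) -> tuple[int, np.ndarray]:
    """Connected-component count/labels of a dense weighted adjacency.

    BFS by matrix-vector reachability; stops early once ``max_label``
    components are found (callers only distinguish 1, 2 or >2).
    """
    n = w.shape[0]
    labels = np.full(n, -1, dtype=np.int64)
    cur = 0
    for seed in range(n):
        if labels[seed] >= 0:
            continue
        comp = np.zeros(n, dtype=bool)
        comp[seed] = True
        frontier = comp.copy()
        while frontier.any():
            reached = (w @ frontier.astype(float)) > 0
            frontier = reached & ~comp
            comp |= frontier
        labels[comp] = cur
        cur += 1
        if cur >= max_label:
            if (labels < 0).any():
                cur += 1                      # at least one more component
            break
    return cur, labels


def ncut_value(w: np.ndarray, mask1: np.ndarray) -> float:
    """Normalized cut of the bipartition given by boolean ``mask1``."""
    cut = w[np.ix_(mask1, ~mask1)].sum()
    if cut == 0:
        return 0.0
    d = w.sum(axis=1)
    return float(cut / d[mask1].sum() + cut / d[~mask1].sum())


def _exact_bipartition(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Global minimum-ncut bipartition by enumeration (n <= ~16)."""
    n = w.shape[0]
    best = (np.inf, None)
    for m in range(1, 1 << (n - 1)):
        mask2 = np.array([(m >> k) & 1 for k in range(n - 1)], dtype=bool)
        mask1 = np.concatenate(([True], ~mask2))
        val = ncut_value(w, mask1)
        if val < best[0]:
            best = (val, mask1)
    return best


def _spectral_bipartition(w: np.ndarray,
                          node_order: Sequence[str]) -> tuple[float, np.ndarray]:
    """Fiedler-vector sweep cut on the normalized affinity.

    Computes the second eigenvector of D^{-1/2} W D^{-1/2}, maps it back to
    the generalized (random-walk) embedding, orders nodes along it — ties
    broken by node id — and returns the minimum-ncut prefix split along that
    ordering.  Deterministic: the Lanczos start vector is fixed.
    """
    n = w.shape[0]
    d = w.sum(axis=1)
    d_safe = np.where(d > 0, d, 1.0)
    inv_sqrt = 1.0 / np.sqrt(d_safe)
    s = w * inv_sqrt[:, None] * inv_sqrt[None, :]
    if n <= 128:
        vals, vecs = np.linalg.eigh(s)
        fiedler = vecs[:, -2]
    else:
        v0 = np.cos(np.arange(n, dtype=float))      # fixed, not an eigenvector
        _, vecs = sp.linalg.eigsh(s, k=2, which="LA", v0=v0, tol=1e-8)
        fiedler = vecs[:, 0] if abs(vecs[:, 1] @ (np.sqrt(d_safe))) > \
            abs(vecs[:, 0] @ (np.sqrt(d_safe))) else vecs[:, 1]
    embed = fiedler * inv_sqrt
    order = sorted(range(n), key=lambda k: (embed[k], node_order[k]))
    ws = w[np.ix_(order, order)]
    ds = d[order]
    total = ds.sum()
    prefix_cross = np.tril(ws, -1).sum(axis=1)      # w to earlier nodes
    cut = 0.0
    best = (np.inf, 1)
    assoc1 = 0.0
    for i in range(1, n):
        k = i - 1                                   # node moving into part 1
        cut += ds[k] - 2.0 * prefix_cross[k]
        assoc1 += ds[k]
        assoc2 = total - assoc1
        if assoc1 <= 0 or assoc2 <= 0:
            val = 0.0 if cut == 0 else np.inf
        else:
            val = cut / assoc1 + cut / assoc2
        if val < best[0]:
            best = (val, i)
    mask1 = np.zeros(n, dtype=bool)
    mask1[order[:best[1]]] = True
    return ncut_value(w, mask1), mask1


def evaluate_node(ng: NeighborGraph, min_degree: int = 4,
                  exact_max: int = EXACT_SEARCH_MAX) -> NodeCut:
    """Partition and score one neighbor graph.

    Returns status ``too_few_neighbors`` below ``min_degree`` neighbors,
    ``unevaluable_components`` when G_a splits into more than two connected
    components, and otherwise the minimum-ncut bipartition found (exact up to
    ``exact_max`` nodes, spectral sweep above).
    """
    n = ng.size
    if n < min_degree:
        return NodeCut(ng.center, "too_few_neighbors")
    n_comp, labels = _dense_components(ng.w)
    if n_comp > 2:
        return NodeCut(ng.center, "unevaluable_components")
    if n_comp == 2:
        mask1 = labels == labels[0]
        return NodeCut(ng.center, "evaluated", ncut=0.0,
                       part1=[ng.nodes[i] for i in np.flatnonzero(mask1)],
                       part2=[ng.nodes[i] for i in np.flatnonzero(~mask1)])
    if n <= exact_max:
        val, mask1 = _exact_bipartition(ng.w)
    else:
        val, mask1 = _spectral_bipartition(ng.w, ng.nodes)
    return NodeCut(ng.center, "evaluated", ncut=float(val),
                   part1=[ng.nodes[i] for i in np.flatnonzero(mask1)],
                   part2=[ng.nodes[i] for i in np.flatnonzero(~mask1)])


def evaluate_all_nodes(g: BipartiteGraph,
                       nodes: Iterable[str] | None = None,
                       min_degree: int = 4,
                       exact_max: int = EXACT_SEARCH_MAX) -> NodeCutTable:
    """Evaluate many centers, sharing the two Gram matrices across nodes.

    For a center in U the w_i2 weights are a principal submatrix of
    A^T A minus the rank-one contribution of the center's own edges, so both
    Grams are computed once and sliced per node.
    """
    node_list = list(nodes) if nodes is not None else g.nodes()
    mat = g.matrix.astype(np.float64)
    density = mat.nnz / max(mat.shape[0] * mat.shape[1], 1)
    if density > 0.02:                         # BLAS beats sparse matmul here
        dense = mat.toarray()
        gram_v = dense.T @ dense if any(n in g.u_index for n in node_list) else None
        gram_u = dense @ dense.T if any(n in g.v_index for n in node_list) else None
        del dense
    else:
        gram_v = (mat.T @ mat).toarray() if any(n in g.u_index for n in node_list) else None
        gram_u = (mat @ mat.T).toarray() if any(n in g.v_index for n in node_list) else None
    table = NodeCutTable()
    csc = mat.tocsc()
    for a in node_list:
        if a in g.u_index:
            row = mat.getrow(g.u_index[a])
            s_idx, w_a = row.indices, row.data
            gram = gram_v
            names = g.v_ids
        else:
            col = csc.getcol(g.v_index[a]).tocoo()
            s_idx, w_a = col.row, col.data
            gram = gram_u
            names = g.u_ids
        w = gram[np.ix_(s_idx, s_idx)] - np.outer(w_a, w_a)
        np.fill_diagonal(w, 0.0)
        ng = NeighborGraph(center=a, nodes=[names[i] for i in s_idx], w=w)
        table[a] = evaluate_node(ng, min_degree=min_degree, exact_max=exact_max)
    return table


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_nodes(g: BipartiteGraph, cuts: NodeCutTable, cutoff: float
                ) -> tuple[BipartiteGraph, dict[str, dict]]:
    """Split every evaluated node with ncut < cutoff into two nodes.

    Each new node (ids ``<node>.1`` / ``<node>.2``) inherits the edges to one
    partition.  Edges whose two endpoints are both split are deleted.  All
    decisions use the pre-split cut table (single pass).  The returned
    split_map records, per split node, the new ids and both partitions;
    downstream joins to ground truth must use it rather than parsing ids.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    to_split = {n: c for n, c in cuts.items()
                if c.status == "evaluated" and c.ncut < cutoff}
    split_map = {n: {"new_1": f"{n}.1", "new_2": f"{n}.2",
                     "part1": list(c.part1), "part2": list(c.part2)}
                 for n, c in to_split.items()}
    part_of = {n: ({x: 1 for x in c.part1} | {x: 2 for x in c.part2})
               for n, c in to_split.items()}

    edges: list[tuple[str, str, int]] = []
    for u, v, w in g.edges():
        su, sv = u in to_split, v in to_split
        if su and sv:
            continue                                # both endpoints split
        if su:
            u = f"{u}.{part_of[u][v]}"
        elif sv:
            v = f"{v}.{part_of[v][u]}"
        edges.append((u, v, w))

    def expand(ids: list[str]) -> list[str]:
        out: list[str] = []
        for n in ids:
            if n in to_split:
                out.extend((f"{n}.1", f"{n}.2"))
            else:
                out.append(n)
        return out

    new_g = BipartiteGraph.from_edges(edges, u_ids=expand(g.u_ids),
                                      v_ids=expand(g.v_ids))
    return new_g, split_map


def write_split_map(split_map: dict[str, dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(split_map, indent=2) + "\n")
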