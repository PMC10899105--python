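"""Weighted bipartite adjacency graphs and the standard pre/post filters.

The universal substrate of the package is a weighted, undirected, bipartite
graph ``G = (U, V, E, w)``: one node per polony (polymerase colony), one edge
per observed polony pair, and integer edge weights equal to the number of
unique event identifiers (UEIs) sequenced for that pair.  ``U`` holds the
"beacon"-type polonies and ``V`` the "target"-type polonies; edges only ever
join opposite types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite
from scipy.sparse.csgraph import connected_components

__all__ = [
    "BipartiteGraph",
    "UEITable",
    "FormatError",
    "ValidationError",
    "load_uei_table",
    "write_uei_table",
    "aggregate",
    "read_count_filter",
    "iterative_low_product_filter",
    "largest_component",
]

UEI_COLUMNS = ("beacon_id", "target_id", "uei_id", "read_count")


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


@dataclass(frozen=True)
class UEITable:
    """Per-concatemer records before aggregation into a graph.

    Each record is one sequenced concatemer: the beacon polony it joins, the
    target polony, its unique event identifier barcode and the number of
    supporting reads.
    """

    records: pd.DataFrame  # columns: beacon_id, target_id, uei_id, read_count

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in UEI_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"UEI table missing columns: {missing}")
        if df["uei_id"].duplicated().any():
            dupes = df.loc[df["uei_id"].duplicated(), "uei_id"].head(5).tolist()
            raise ValidationError(f"duplicate uei_id values (e.g. {dupes})")
        if len(df) and (df["read_count"] < 1).any():
            bad = df.index[df["read_count"] < 1][:5].tolist()
            raise ValidationError(f"non-positive read_count at rows {bad}")

    def __len__(self) -> int:
        return len(self.records)


class BipartiteGraph:
    """Weighted bipartite graph with positive integer edge weights.

    Internally backed by a CSR matrix with rows = sorted beacon (U) ids and
    columns = sorted target (V) ids, which is also the fixed convention for
    adjacency export.  Absent pairs have weight 0; stored weights are >= 1.
    """

    def __init__(self, u_ids: Iterable[str], v_ids: Iterable[str],
                 matrix: sp.spmatrix | np.ndarray | None = None):
        self.u_ids: list[str] = sorted(map(str, u_ids))
        self.v_ids: list[str] = sorted(map(str, v_ids))
        overlap = set(self.u_ids) & set(self.v_ids)
        if overlap:
            raise ValidationError(
                f"node ids on both sides of the bipartition: {sorted(overlap)[:5]}")
        if len(set(self.u_ids)) != len(self.u_ids) or len(set(self.v_ids)) != len(self.v_ids):
            raise ValidationError("duplicate node ids within a bipartition side")
        self.u_index: dict[str, int] = {u: i for i, u in enumerate(self.u_ids)}
        self.v_index: dict[str, int] = {v: i for i, v in enumerate(self.v_ids)}
        if matrix is None:
            matrix = sp.csr_matrix((len(self.u_ids), len(self.v_ids)), dtype=np.int64)
        mat = sp.csr_matrix(matrix, dtype=np.int64)
        if mat.shape != (len(self.u_ids), len(self.v_ids)):
            raise ValidationError(
                f"matrix shape {mat.shape} does not match node counts "
                f"({len(self.u_ids)}, {len(self.v_ids)})")
        mat.eliminate_zeros()
        if mat.nnz and mat.data.min() < 1:
            raise ValidationError("edge weights must be positive integers")
        mat.sort_indices()
        self.matrix: sp.csr_matrix = mat

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, int]],
                   u_ids: Iterable[str] | None = None,
                   v_ids: Iterable[str] | None = None) -> "BipartiteGraph":
        """Build from (u, v, weight) triples; duplicate pairs are summed."""
        edges = list(edges)
        us = set(u_ids) if u_ids is not None else {e[0] for e in edges}
        vs = set(v_ids) if v_ids is not None else {e[1] for e in edges}
        g = cls(us, vs)
        if edges:
            rows = [g.u_index[u] for u, _, _ in edges]
            cols = [g.v_index[v] for _, v, _ in edges]
            w = [int(x) for _, _, x in edges]
            if min(w) < 1:
                raise ValidationError("edge weights must be >= 1")
            mat = sp.coo_matrix((w, (rows, cols)),
                                shape=(len(g.u_ids), len(g.v_ids)), dtype=np.int64)
            g = cls(g.u_ids, g.v_ids, mat.tocsr())
        return g

    # -- basic queries ------------------------------------------------------

    @property
    def n_u(self) -> int:
        return len(self.u_ids)

    @property
    def n_v(self) -> int:
        return len(self.v_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_u + self.n_v

    @property
    def n_edges(self) -> int:
        return int(self.matrix.nnz)

    @property
    def total_weight(self) -> int:
        return int(self.matrix.data.sum()) if self.matrix.nnz else 0

    def nodes(self) -> list[str]:
        return self.u_ids + self.v_ids

    def side(self, node: str) -> str:
        if node in self.u_index:
            return "U"
        if node in self.v_index:
            return "V"
        raise KeyError(node)

    def weight(self, u: str, v: str) -> int:
        """Weight of the (u, v) pair; 0 if absent.  Order-insensitive."""
        if u in self.v_index and v in self.u_index:
            u, v = v, u
        return int(self.matrix[self.u_index[u], self.v_index[v]])

    def degree(self, node: str) -> int:
        """Number of distinct neighbors of ``node``."""
        if node in self.u_index:
            row = self.matrix.getrow(self.u_index[node])
            return int(row.nnz)
        col = self.matrix.getcol(self.v_index[node])
        return int(col.nnz)

    def strength(self, node: str) -> int:
        """Total incident weight of ``node`` (its UEI / product count)."""
        if node in self.u_index:
            return int(self.matrix.getrow(self.u_index[node]).sum())
        return int(self.matrix.getcol(self.v_index[node]).sum())

    def edges(self) -> Iterator[tuple[str, str, int]]:
        coo = self.matrix.tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield self.u_ids[i], self.v_ids[j], int(w)

    def edge_dict(self) -> dict[tuple[str, str], int]:
        return {(u, v): w for u, v, w in self.edges()}

    def neighbors(self, node: str) -> list[str]:
        if node in self.u_index:
            row = self.matrix.getrow(self.u_index[node])
            return [self.v_ids[j] for j in row.indices]
        col = self.matrix.getcol(self.v_index[node]).tocoo()
        return [self.u_ids[i] for i in col.row]

    # -- derived graphs -----------------------------------------------------

    def subgraph(self, keep_nodes: Iterable[str]) -> "BipartiteGraph":
        keep = set(keep_nodes)
        u_keep = [i for i, u in enumerate(self.u_ids) if u in keep]
        v_keep = [j for j, v in enumerate(self.v_ids) if v in keep]
        mat = self.matrix[np.ix_(u_keep, v_keep)] if u_keep and v_keep else None
        g = BipartiteGraph([self.u_ids[i] for i in u_keep],
                           [self.v_ids[j] for j in v_keep])
        if mat is not None:
            g = BipartiteGraph(g.u_ids, g.v_ids, mat)
        return g

    def copy(self) -> "BipartiteGraph":
        return BipartiteGraph(self.u_ids, self.v_ids, self.matrix.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteGraph):
            return NotImplemented
        return (self.u_ids == other.u_ids and self.v_ids == other.v_ids
                and (self.matrix != other.matrix).nnz == 0)

    def __repr__(self) -> str:
        return (f"BipartiteGraph(|U|={self.n_u}, |V|={self.n_v}, "
                f"edges={self.n_edges}, total_weight={self.total_weight})")

    # -- I/O ----------------------------------------------------------------

    def to_edge_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(list(self.edges()), columns=["u_id", "v_id", "weight"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_edge_tsv(cls, path: str | Path) -> "BipartiteGraph":
        df = pd.read_csv(path, sep="\t", dtype={"u_id": str, "v_id": str})
        missing = [c for c in ("u_id", "v_id", "weight") if c not in df.columns]
        if missing:
            raise FormatError(f"edge list missing columns: {missing}")
        return cls.from_edges(df.itertuples(index=False, name=None))

    def to_mtx(self, path: str | Path) -> None:
        """Matrix Market export plus ``<path>.u.txt`` / ``<path>.v.txt`` orders."""
        path = Path(path)
        mmwrite(str(path), self.matrix)
        path.with_suffix(path.suffix + ".u.txt").write_text(
            "\n".join(self.u_ids) + ("\n" if self.u_ids else ""))
        path.with_suffix(path.suffix + ".v.txt").write_text(
            "\n".join(self.v_ids) + ("\n" if self.v_ids else ""))

    def metadata(self) -> dict:
        return {"n_beacons": self.n_u, "n_targets": self.n_v,
                "n_edges": self.n_edges, "total_ueis": self.total_weight}

    def write_metadata(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# UEI table I/O and aggregation
# ---------------------------------------------------------------------------

def load_uei_table(path: str | Path) -> UEITable:
    """Read a UEI table from TSV.

    Expects header columns ``beacon_id, target_id, uei_id, read_count``.
    Malformed rows are reported with 1-based line numbers (header = line 1).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={
            "beacon_id": str, "target_id": str, "uei_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header row") from exc
    missing = [c for c in UEI_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    counts = pd.to_numeric(df["read_count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValidationError(
            f"{path}: invalid read_count on line(s) {lines}")
    df = df.assign(read_count=counts.astype(np.int64))
    return UEITable(df[list(UEI_COLUMNS)].copy())


def write_uei_table(table: UEITable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def aggregate(table: UEITable) -> BipartiteGraph:
    """Aggregate a UEI table into a bipartite graph.

    The edge weight of a (beacon, target) pair is the number of distinct UEIs
    observed for it — read counts are *not* summed into weights.
    """
    df = table.records
    beacons = set(df["beacon_id"])
    targets = set(df["target_id"])
    both = beacons & targets
    if both:
        raise ValidationError(
            f"ids appear as both beacon and target: {sorted(both)[:5]}")
    if df.empty:
        return BipartiteGraph([], [])
    counts = df.groupby(["beacon_id", "target_id"], sort=False).size()
    edges = [(b, t, int(n)) for (b, t), n in counts.items()]
    return BipartiteGraph.from_edges(edges, u_ids=beacons, v_ids=targets)


def read_count_filter(table: UEITable, min_reads: int) -> UEITable:
    """Keep only records supported by at least ``min_reads`` reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    df = table.records
    return UEITable(df[df["read_count"] >= min_reads].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Graph-level filters
# ---------------------------------------------------------------------------

def iterative_low_product_filter(g: BipartiteGraph,
                                 min_products: int = 2) -> BipartiteGraph:
    """Iteratively drop nodes with fewer than ``min_products`` incident UEIs.

    A node's product count is its total incident edge weight (each UEI is one
    sequenced product).  Removal cascades until a fixed point; the result is
    independent of removal order because all sub-threshold nodes are removed
    simultaneously in each round.
    """
    mat = g.matrix.copy()
    u_keep = np.arange(g.n_u)
    v_keep = np.arange(g.n_v)
    while True:
        row_str = np.asarray(mat.sum(axis=1)).ravel()
        col_str = np.asarray(mat.sum(axis=0)).ravel()
        u_ok = row_str >= min_products
        v_ok = col_str >= min_products
        if u_ok.all() and v_ok.all():
            break
        u_keep = u_keep[u_ok]
        v_keep = v_keep[v_ok]
        mat = mat[np.ix_(np.flatnonzero(u_ok), np.flatnonzero(v_ok))]
        if mat.shape[0] == 0 or mat.shape[1] == 0:
            # one empty side leaves the other with zero products -> all go
            return BipartiteGraph([], [])
    return BipartiteGraph([g.u_ids[i] for i in u_keep],
                          [g.v_ids[j] for j in v_keep], mat)


def _component_labels(g: BipartiteGraph) -> np.ndarray:
    """Connected-component label per node, U nodes first then V nodes."""
    n = g.n_nodes
    adj = sp.bmat([[None, g.matrix], [g.matrix.T, None]], format="csr")
    if adj is None or n == 0:
        return np.zeros(0, dtype=int)
    _, labels = connected_components(adj, directed=False)
    return labels


def largest_component(g: BipartiteGraph) -> tuple[BipartiteGraph, float]:
    """Induced subgraph on the largest connected component and its node share.

    Ties between equally large components are broken by the smallest
    lexicographic node id they contain.  An empty graph maps to itself with
    fraction 0.  Downstream, datasets whose fraction falls below 0.8 are
    treated as non-reconstructable.
    """
    if g.n_nodes == 0:
        return g, 0.0
    labels = _component_labels(g)
    all_ids = g.nodes()
    sizes = np.bincount(labels)
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) > 1:
        # smallest lexicographic member id wins
        rep = {c: min(all_ids[i] for i in np.flatnonzero(labels == c))
               for c in candidates}
        winner = min(candidates, key=lambda c: rep[c])
    else:
        winner = candidates[0]
    keep = [all_ids[i] for i in np.flatnonzero(labels == winner)]
    return g.subgraph(keep), best / g.n_nodes
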