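"""Quality and detection metrics.

Global reconstruction quality: Procrustes disparity — both point sets are
centered and unit-scaled, optimally aligned by an orthogonal transform
(reflections allowed, since graph reconstructions have arbitrary chirality),
and the residual sum of squares is reported.  Local quality: mean k-nearest-
neighbor overlap between the two layouts (default k = 15).

Split accuracy: each recovered partition of a split node is matched to its
best of the two true pre-fusion neighbor sets by contained fraction, and the
two best fractions are averaged:

    overlap = ( max(|S_a1 ∩ S_b|, |S_a1 ∩ S_c|) / |S_a1|
              + max(|S_a2 ∩ S_b|, |S_a2 ∩ S_c|) / |S_a2| ) / 2

A symmetric Jaccard variant is provided for comparison.  Detection rates
compare removed edges / split nodes against the injection ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import procrustes as _procrustes
from sklearn.neighbors import NearestNeighbors

from .simulate import ErrorLedger
from .reconstruct import Layout

__all__ = [
    "QualityReport",
    "DetectionReport",
    "procrustes_disparity",
    "knn_overlap",
    "split_overlap",
    "split_jaccard",
    "detection_rates",
    "quality_report",
]


@dataclass
class QualityReport:
    procrustes_disparity: float
    knn_overlap: float
    n_nodes_evaluated: int
    component_fraction: float = 1.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class DetectionReport:
    edge_tp_fraction: float | None = None
    edge_fp_fraction: float | None = None
    node_tp_fraction: float | None = None
    node_fp_fraction: float | None = None
    split_overlap_mean: float | None = None
    n_unevaluable: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _common(ref: Layout, test: Layout) -> list[str]:
    common = sorted(set(ref.ids) & set(test.ids))
    return common


def procrustes_disparity(ref: Layout, test: Layout) -> float:
    """Standardized Procrustes disparity between two layouts.

    Point sets are intersected on common node ids, centered, unit-scaled and
    optimally rotated/reflected onto each other; returns the residual sum of
    squares.  0 means identical up to a similarity transform.
    """
    common = _common(ref, test)
    if len(common) < 3:
        raise ValueError(f"need >= 3 common nodes, have {len(common)}")
    _, _, disparity = _procrustes(ref.subset(common), test.subset(common))
    return float(disparity)


def knn_overlap(ref: Layout, test: Layout, k: int = 15) -> float:
    """Mean fraction of shared k-nearest neighbors across the two layouts.

    Euclidean metric, self excluded.  1.0 means every node keeps its entire
    local neighborhood; a random layout scores about k / (n - 1).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    common = _common(ref, test)
    n = len(common)
    if n <= k:
        raise ValueError(f"need more than k={k} common nodes, have {n}")
    overlaps = []
    sets = []
    for layout in (ref, test):
        pts = layout.subset(common)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        idx = nn.kneighbors(pts, return_distance=False)[:, 1:]
        sets.append(idx)
    a, b = sets
    for i in range(n):
        overlaps.append(len(set(a[i]) & set(b[i])) / k)
    return float(np.mean(overlaps))


def split_overlap(parts: tuple[Iterable[str], Iterable[str]],
                  truth: tuple[Iterable[str], Iterable[str]]) -> float:
    """Best-match contained-fraction overlap of a recovered split (see module doc)."""
    (p1, p2), (tb, tc) = (tuple(map(set, parts)), tuple(map(set, truth)))
    if not p1 or not p2:
        raise ValueError("recovered partitions must be nonempty")
    total = 0.0
    for p in (p1, p2):
        total += max(len(p & tb), len(p & tc)) / len(p)
    return total / 2.0


def split_jaccard(parts: tuple[Iterable[str], Iterable[str]],
                  truth: tuple[Iterable[str], Iterable[str]]) -> float:
    """Symmetric Jaccard variant: best pairing of parts to truth sets."""
    (p1, p2), (tb, tc) = (tuple(map(set, parts)), tuple(map(set, truth)))
    if not p1 or not p2:
        raise ValueError("recovered partitions must be nonempty")

    def jac(x: set, y: set) -> float:
        return len(x & y) / len(x | y) if x | y else 1.0

    direct = (jac(p1, tb) + jac(p2, tc)) / 2
    swapped = (jac(p1, tc) + jac(p2, tb)) / 2
    return max(direct, swapped)


def detection_rates(ledger: ErrorLedger,
                    removed_edges: Sequence[tuple[str, str, int]] | None = None,
                    original_edges: Sequence[tuple[str, str]] | None = None,
                    split_nodes: Iterable[str] | None = None,
                    all_nodes: Iterable[str] | None = None,
                    split_map: dict[str, dict] | None = None,
                    id_map: dict[str, str] | None = None) -> DetectionReport:
    """TP/FP rates of edge removal and node splitting against the ledger.

    Edge TP: removed pair that is a ledgered pure crosslink (no pre-injection
    weight); edge FP: removed pair that existed before injection.  Node TP:
    split node ledgered as a fusion; node FP: split unaltered node.  TP
    fractions are normalized by the ledgered-error counts, FP fractions by the
    original-item counts.  ``id_map`` translates ledger-era ids to current ids
    (after other corrections), defaulting to identity.
    """
    id_map = id_map or {}
    report = DetectionReport()
    if removed_edges is not None:
        if original_edges is None:
            raise ValueError("original_edges required with removed_edges")
        original = {(u, v) for u, v in original_edges}
        spurious = {(u, v) for u, v in ledger.crosslink_pairs()
                    if (u, v) not in original}
        removed_pairs = {(u, v) for u, v, *_ in removed_edges}
        orphans = [p for p in removed_pairs
                   if p not in original and p not in spurious]
        if orphans:
            raise ValueError(f"removed edges not in graph lineage: {orphans[:5]}")
        tp = len(removed_pairs & spurious)
        fp = len(removed_pairs & original)
        report.edge_tp_fraction = tp / len(spurious) if spurious else 0.0
        report.edge_fp_fraction = fp / len(original) if original else 0.0
    if split_nodes is not None:
        if all_nodes is None:
            raise ValueError("all_nodes required with split_nodes")
        split_set = set(split_nodes)
        fused = {id_map.get(f.fused_id, f.fused_id) for f in ledger.fusions}
        normal = set(all_nodes) - fused
        orphans = sorted(split_set - fused - normal)
        if orphans:
            raise ValueError(f"split nodes not in graph lineage: {orphans[:5]}")
        tp = len(split_set & fused)
        fp = len(split_set & normal)
        report.node_tp_fraction = tp / len(fused) if fused else 0.0
        report.node_fp_fraction = fp / len(normal) if normal else 0.0
        if split_map is not None:
            overlaps = []
            recs = {f.fused_id: f for f in ledger.fusions}
            for fused_id, rec in recs.items():
                current = id_map.get(fused_id, fused_id)
                if current not in split_map:
                    continue
                entry = split_map[current]
                truth = ([id_map.get(i, i) for i in rec.neighbors_1],
                         [id_map.get(i, i) for i in rec.neighbors_2])
                overlaps.append(split_overlap(
                    (entry["part1"], entry["part2"]), truth))
            report.split_overlap_mean = (float(np.mean(overlaps))
                                         if overlaps else None)
    return report


def quality_report(truth: Layout, recon: Layout, k: int = 15,
                   component_fraction: float = 1.0) -> QualityReport:
    common = _common(truth, recon)
    return QualityReport(
        procrustes_disparity=procrustes_disparity(truth, recon),
        knn_overlap=knn_overlap(truth, recon, k=k),
        n_nodes_evaluated=len(common),
        component_fraction=component_fraction)
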