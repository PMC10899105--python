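"""Diffusion-based adjacency simulator and error injectors.

Polony formation in a hydrogel is diffusion-limited: the rate at which two
polonies react falls off as a Gaussian in their distance, with a length scale
set by the diffusion constant and reaction time (L_diff = sqrt(8 d D t)).
The simulator draws, for every opposite-type pair (i, j), an integer edge
weight

    w(i, j) ~ Poisson( a * exp(-|x_i - x_j|^2 / sigma^2) )

where ``a`` (amplitude) lumps polony reactivity and sequencing depth and
``sigma`` (spread) plays the role of L_diff.  Pairs drawing 0 produce no edge;
same-type pairs are never connected.

Three experimental artifact types can then be injected, each with a complete
ground-truth ledger:

* spurious crosslinks — unit-weight edges between uniformly random U/V nodes,
  regardless of distance (chimeric PCR after lysis);
* fused nodes — two same-type nodes merged into one that inherits both edge
  sets (barcode collisions / over-eager barcode error correction);
* reactivity bias — selected nodes form products at a multiplied rate
  (a per-node factor on the Poisson mean).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import BipartiteGraph, ValidationError

__all__ = [
    "SimScene",
    "SimParams",
    "ErrorLedger",
    "FusionRecord",
    "place_nodes",
    "simulate_graph",
    "inject_spurious_crosslinks",
    "inject_fused_nodes",
    "inject_reactivity_bias",
    "replicate_edge_weights",
    "elliptical_mask",
    "DEFAULT_MASK",
    "DEFAULT_N_NODES",
]

#: Default simulation region: full rectangle, width x height in pixels.
DEFAULT_MASK: tuple[int, int] = (200, 450)
#: Default number of polonies in a scene.
DEFAULT_N_NODES: int = 4000


def elliptical_mask(grid: tuple[int, int] = DEFAULT_MASK,
                    area: float = 40_000.0) -> np.ndarray:
    """Boolean pixel mask of an ellipse of the given area inside ``grid``.

    The standard study region is a ~40,000 px^2 tissue-like shape inside the
    200 x 450 px grid, i.e. ~4,000 polonies at a density of ~0.1 /px^2; the
    ellipse is a synthetic stand-in with the grid's aspect ratio.
    """
    w, h = grid
    ry = np.sqrt(area * (h / w) / np.pi)
    rx = ry * w / h
    yy, xx = np.mgrid[0:h, 0:w]
    return (((xx - w / 2) / rx) ** 2 + ((yy - h / 2) / ry) ** 2) <= 1.0


def _rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimParams:
    """Amplitude/spread of the Gaussian Poisson-mean kernel.

    ``sigma`` may be given directly (in pixels) or derived from physical
    parameters as sqrt(8 * d * D * t); if both are given they must agree to
    relative tolerance 1e-9.
    """

    a: float
    sigma: float | None = None
    D: float | None = None      # diffusion constant, px^2 / time
    t: float | None = None      # time since polony creation
    d: int | None = None        # spatial dimensionality

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("amplitude a must be >= 0")
        # a == 0 is the degenerate edgeless model; allowed for completeness
        physical = (self.D, self.t, self.d)
        if self.sigma is None and any(p is None for p in physical):
            raise ValueError("give sigma, or all of D, t, d")
        if all(p is not None for p in physical):
            derived = math.sqrt(8 * self.d * self.D * self.t)
            if self.sigma is None:
                object.__setattr__(self, "sigma", derived)
            elif not math.isclose(self.sigma, derived, rel_tol=1e-9):
                raise ValueError(
                    f"sigma={self.sigma} inconsistent with sqrt(8dDt)={derived}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class SimScene:
    """Ground-truth node placement: ids, coordinates, and type per node."""

    ids: list[str]
    xy: np.ndarray            # (n, 2) float64, pixels
    types: np.ndarray         # (n,) of "U" / "V"
    mask: tuple[int, int] | np.ndarray = DEFAULT_MASK
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def u_ids(self) -> list[str]:
        return [i for i, t in zip(self.ids, self.types) if t == "U"]

    @property
    def v_ids(self) -> list[str]:
        return [i for i, t in zip(self.ids, self.types) if t == "V"]

    def coordinates(self) -> dict[str, np.ndarray]:
        return {i: self.xy[k] for k, i in enumerate(self.ids)}

    def layout_array(self, ids: Sequence[str]) -> np.ndarray:
        """Coordinates for ``ids`` (in that order) as an (m, 2) array."""
        index = {i: k for k, i in enumerate(self.ids)}
        return self.xy[[index[i] for i in ids]]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"node_id": self.ids, "type": self.types,
                      "x": self.xy[:, 0], "y": self.xy[:, 1]}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 mask: tuple[int, int] | np.ndarray = DEFAULT_MASK) -> "SimScene":
        df = pd.read_csv(path, sep="\t", dtype={"node_id": str, "type": str})
        return cls(ids=df["node_id"].tolist(),
                   xy=df[["x", "y"]].to_numpy(float),
                   types=df["type"].to_numpy(str), mask=mask)


@dataclass
class FusionRecord:
    """One fusion event: the merged node and its two constituents.

    Neighbor sets are recorded at injection time so split partitions can later
    be scored against the true pre-fusion adjacency.
    """

    fused_id: str
    original_1: str
    original_2: str
    neighbors_1: list[str] = field(default_factory=list)
    neighbors_2: list[str] = field(default_factory=list)


@dataclass
class ErrorLedger:
    """Ground truth of injected artifacts."""

    crosslinks: list[tuple[str, str, int]] = field(default_factory=list)
    fusions: list[FusionRecord] = field(default_factory=list)
    biased: list[tuple[str, float]] = field(default_factory=list)

    def crosslink_pairs(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, _ in self.crosslinks}

    def fusion_map(self) -> dict[str, tuple[str, str]]:
        return {f.fused_id: (f.original_1, f.original_2) for f in self.fusions}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "crosslinks": [[u, v, int(w)] for u, v, w in self.crosslinks],
            "fusions": [{"fused_id": f.fused_id,
                         "original_1": f.original_1,
                         "original_2": f.original_2,
                         "neighbors_1": f.neighbors_1,
                         "neighbors_2": f.neighbors_2} for f in self.fusions],
            "biased": [[n, float(b)] for n, b in self.biased],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ErrorLedger":
        payload = json.loads(Path(path).read_text())
        return cls(
            crosslinks=[(u, v, int(w)) for u, v, w in payload["crosslinks"]],
            fusions=[FusionRecord(**f) for f in payload["fusions"]],
            biased=[(n, float(b)) for n, b in payload["biased"]],
        )


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def place_nodes(mask: tuple[int, int] | np.ndarray = DEFAULT_MASK,
                n_nodes: int = DEFAULT_N_NODES,
                type_fraction: float = 0.5,
                seed: int | np.random.Generator = 0) -> SimScene:
    """Uniformly place ``n_nodes`` typed nodes inside the mask.

    ``mask`` is either a (width, height) rectangle or a boolean pixel grid
    (True = inside).  Each node is independently typed "U" with probability
    ``type_fraction``.  Node ids are zero-padded so lexicographic order equals
    placement order.
    """
    if not 0 < type_fraction < 1:
        raise ValueError("type_fraction must be in (0, 1)")
    rng = _rng(seed)
    if isinstance(mask, np.ndarray):
        inside = np.argwhere(mask)
        if len(inside) == 0:
            raise ValueError("mask has zero area")
        picks = inside[rng.integers(0, len(inside), n_nodes)]
        # uniform within each chosen pixel; argwhere gives (row=y, col=x)
        xy = picks[:, ::-1].astype(float) + rng.random((n_nodes, 2))
    else:
        w, h = mask
        if w <= 0 or h <= 0:
            raise ValueError("mask has zero area")
        xy = rng.random((n_nodes, 2)) * np.array([w, h], dtype=float)
    is_u = rng.random(n_nodes) < type_fraction
    width = max(5, len(str(max(n_nodes - 1, 0))))
    ids = [f"{'b' if u else 't'}{k:0{width}d}" for k, u in enumerate(is_u)]
    types = np.where(is_u, "U", "V")
    return SimScene(ids=ids, xy=xy, types=types, mask=mask,
                    seed=seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# Graph simulation
# ---------------------------------------------------------------------------

def _mean_matrix(scene: SimScene, params: SimParams,
                 node_factors: dict[str, float] | None = None,
                 distance_cutoff: float | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Poisson mean for every (U, V) pair, rows/cols in sorted-id order."""
    u_ids = sorted(scene.u_ids)
    v_ids = sorted(scene.v_ids)
    xu = scene.layout_array(u_ids)
    xv = scene.layout_array(v_ids)
    d2 = (np.add.outer((xu ** 2).sum(axis=1), (xv ** 2).sum(axis=1))
          - 2.0 * xu @ xv.T)
    np.maximum(d2, 0.0, out=d2)
    mean = params.a * np.exp(-d2 / params.sigma ** 2)
    if distance_cutoff is not None:
        mean[d2 > distance_cutoff ** 2] = 0.0
    if node_factors:
        fu = np.array([node_factors.get(i, 1.0) for i in u_ids])
        fv = np.array([node_factors.get(i, 1.0) for i in v_ids])
        mean = mean * fu[:, None] * fv[None, :]
    return mean, u_ids, v_ids


def _draw_graph(mean: np.ndarray, u_ids: list[str], v_ids: list[str],
                rng: np.random.Generator) -> BipartiteGraph:
    w = rng.poisson(mean)
    return BipartiteGraph(u_ids, v_ids, sp.csr_matrix(w))


def simulate_graph(scene: SimScene, params: SimParams,
                   seed: int | np.random.Generator = 0,
                   distance_cutoff: float | None = None) -> BipartiteGraph:
    """Draw a bipartite adjacency graph from the Gaussian-kernel Poisson model.

    ``distance_cutoff`` optionally zeroes means beyond that distance (a speed
    knob for very large scenes; leave ``None`` to evaluate every pair).
    """
    mean, u_ids, v_ids = _mean_matrix(scene, params,
                                      distance_cutoff=distance_cutoff)
    return _draw_graph(mean, u_ids, v_ids, _rng(seed))


def replicate_edge_weights(a: float, sigma: float, dist: float,
                           n_draws: int, seed: int | np.random.Generator = 0,
                           pairs_per_scene: int = 250) -> np.ndarray:
    """Replicate edge-weight draws for one U–V pair at fixed distance.

    Builds scenes of isolated U/V pairs separated by 100 sigma (so cross-pair
    Poisson means underflow to exactly zero) and collects the weight drawn
    for each pair, running scenes until ``n_draws`` draws are available.
    Used to calibrate the simulator against the closed-form mean
    a * exp(-dist^2 / sigma^2).
    """
    rng = _rng(seed)
    spacing = 100.0 * sigma + dist
    side = int(np.ceil(np.sqrt(pairs_per_scene)))
    anchors = np.array([(i * spacing, j * spacing)
                        for i in range(side) for j in range(side)]
                       )[:pairs_per_scene]
    n = len(anchors)
    ids = [f"{'b' if k % 2 == 0 else 't'}{k // 2:05d}" for k in range(2 * n)]
    xy = np.empty((2 * n, 2))
    xy[0::2] = anchors
    xy[1::2] = anchors + np.array([dist, 0.0])
    types = np.array(["U", "V"] * n)
    scene = SimScene(ids=ids, xy=xy, types=types,
                     mask=(spacing * side, spacing * side))
    params = SimParams(a=a, sigma=sigma)
    mean, u_ids, v_ids = _mean_matrix(scene, params)
    # pair k is (sorted U id k, sorted V id k) by construction
    draws: list[np.ndarray] = []
    got = 0
    while got < n_draws:
        w = rng.poisson(mean)
        draws.append(np.diagonal(w).copy())
        got += n
    return np.concatenate(draws)[:n_draws]


# ---------------------------------------------------------------------------
# Error injectors
# ---------------------------------------------------------------------------

def inject_spurious_crosslinks(g: BipartiteGraph, fraction: float,
                               seed: int | np.random.Generator = 0
                               ) -> tuple[BipartiteGraph, ErrorLedger]:
    """Add ``round(fraction * total_weight)`` unit-weight random crosslinks.

    Each event independently picks a uniform U node and a uniform V node; if
    the pair already carries weight, the weight is incremented and the event
    is still ledgered.  The ledger aggregates events per pair as
    (u, v, added_weight).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if g.n_u == 0 or g.n_v == 0:
        raise ValidationError("cannot inject crosslinks into an empty graph")
    n_events = int(round(fraction * g.total_weight))
    if n_events == 0:
        return g.copy(), ErrorLedger()
    rng = _rng(seed)
    ui = rng.integers(0, g.n_u, n_events)
    vi = rng.integers(0, g.n_v, n_events)
    flat = ui.astype(np.int64) * g.n_v + vi
    counts = np.bincount(flat, minlength=0)
    nz = np.flatnonzero(counts)
    add = sp.coo_matrix((counts[nz], (nz // g.n_v, nz % g.n_v)),
                        shape=g.matrix.shape, dtype=np.int64).tocsr()
    ledger = ErrorLedger(crosslinks=[
        (g.u_ids[i], g.v_ids[j], int(c))
        for i, j, c in zip(nz // g.n_v, nz % g.n_v, counts[nz])])
    return BipartiteGraph(g.u_ids, g.v_ids, g.matrix + add), ledger


def inject_fused_nodes(g: BipartiteGraph, fraction: float,
                       seed: int | np.random.Generator = 0
                       ) -> tuple[BipartiteGraph, ErrorLedger]:
    """Fuse ``round(fraction * n_nodes)`` uniformly sampled same-type pairs.

    Each event draws one unordered pair uniformly from all pairs of not-yet-
    fused same-type nodes (so the side is chosen with probability proportional
    to its number of eligible pairs).  The fused node inherits the per-neighbor
    summed weights of both constituents and is itself ineligible for further
    fusion.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    n_events = int(round(fraction * g.n_nodes))
    if n_events == 0:
        return g.copy(), ErrorLedger()
    rng = _rng(seed)
    eligible = {"U": list(g.u_ids), "V": list(g.v_ids)}
    pairs: list[tuple[str, str, str]] = []  # (side, id1, id2)
    for _ in range(n_events):
        n_u, n_v = len(eligible["U"]), len(eligible["V"])
        w_u, w_v = n_u * (n_u - 1) // 2, n_v * (n_v - 1) // 2
        if w_u + w_v == 0:
            raise ValidationError(
                f"not enough unfused same-type nodes for {n_events} fusion "
                f"events (ran out after {len(pairs)})")
        side = "U" if rng.random() < w_u / (w_u + w_v) else "V"
        pool = eligible[side]
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        for x in sorted((i, j), reverse=True):
            pool.pop(x)
        pairs.append((side, a, b))

    fusion_map: dict[str, str] = {}
    records: list[FusionRecord] = []
    for side, a, b in pairs:
        fused = f"{a}+{b}"
        fusion_map[a] = fused
        fusion_map[b] = fused
        records.append(FusionRecord(
            fused_id=fused, original_1=a, original_2=b,
            neighbors_1=g.neighbors(a), neighbors_2=g.neighbors(b)))

    new_u = sorted({fusion_map.get(u, u) for u in g.u_ids})
    new_v = sorted({fusion_map.get(v, v) for v in g.v_ids})
    u_pos = {u: k for k, u in enumerate(new_u)}
    v_pos = {v: k for k, v in enumerate(new_v)}
    # row/col merge via permutation-sum projectors
    pu = sp.coo_matrix(
        (np.ones(g.n_u), ([u_pos[fusion_map.get(u, u)] for u in g.u_ids],
                          range(g.n_u))), shape=(len(new_u), g.n_u))
    pv = sp.coo_matrix(
        (np.ones(g.n_v), (range(g.n_v),
                          [v_pos[fusion_map.get(v, v)] for v in g.v_ids])),
        shape=(g.n_v, len(new_v)))
    mat = (pu.tocsr() @ g.matrix @ pv.tocsr()).astype(np.int64)
    return BipartiteGraph(new_u, new_v, mat), ErrorLedger(fusions=records)


def inject_reactivity_bias(scene: SimScene, params: SimParams,
                           node_fraction: float, bias_factor: float = 2.0,
                           seed: int | np.random.Generator = 0
                           ) -> tuple[BipartiteGraph, ErrorLedger]:
    """Simulate a graph in which selected nodes react at a multiplied rate.

    A fraction of nodes is marked biased; every pair's Poisson mean is
    multiplied by ``bias_factor`` once per biased endpoint.  With
    ``node_fraction == 0`` and the same seed this reproduces
    :func:`simulate_graph` exactly, because node selection and edge drawing
    use independent child streams of the seed.
    """
    if bias_factor <= 0:
        raise ValueError("bias_factor must be > 0")
    if not 0 <= node_fraction <= 1:
        raise ValueError("node_fraction must be in [0, 1]")
    if isinstance(seed, int):
        # drawing uses the same stream as simulate_graph(seed) so that
        # node_fraction 0 reproduces it bit-for-bit; node picking uses a
        # spawned child stream to stay independent of the draw
        draw_rng = np.random.default_rng(seed)
        pick_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    else:
        pick_rng = draw_rng = _rng(seed)
    n_biased = int(round(node_fraction * scene.n_nodes))
    chosen = (sorted(pick_rng.choice(scene.ids, size=n_biased, replace=False))
              if n_biased else [])
    factors = {i: bias_factor for i in chosen}
    mean, u_ids, v_ids = _mean_matrix(scene, params, node_factors=factors)
    graph = _draw_graph(mean, u_ids, v_ids, draw_rng)
    return graph, ErrorLedger(biased=[(i, bias_factor) for i in chosen])
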