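"""Config-driven orchestration of simulation sweeps and the filter chain.

Two workflows are wired here:

* simulation sweeps — generate scenes on an (amplitude x spread) grid, inject
  one artifact type at one or more fractions, optionally correct, reconstruct
  what passes the 80%-connectivity rule, and tabulate detection and quality
  metrics per cell;
* the experimental chain — aggregate a UEI table, apply either a read-count
  or an indirect-path filter, then the iterative <2-product filter and the
  largest connected component, and report the surviving UEI/edge/polony
  counts.

The sweep defaults are the package's standard study conditions: ~4,000 nodes
placed uniformly in a ~40,000 px^2 elliptical region of the 200 x 450 px
grid (node density ~0.1 /px^2), amplitudes {1, 10, 100}, spreads
{20, 50, 100}, fused-node fractions {1%, 5%, 20%} and a 20% crosslink
fraction.  Simulated graphs are not passed through the iterative <2-product
filter (that filter exists for sequencing-error artifacts in experimental
data); the guideline cutoff for correction is the expected error fraction
used as a quantile.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .graph import (BipartiteGraph, UEITable, aggregate, load_uei_table,
                    iterative_low_product_filter, largest_component,
                    read_count_filter)
from .simulate import (DEFAULT_MASK, DEFAULT_N_NODES, SimParams,
                       elliptical_mask, place_nodes, simulate_graph,
                       inject_fused_nodes, inject_spurious_crosslinks,
                       inject_reactivity_bias)
from .crosslinks import (indirect_path_values, quantile_cutoff, filter_edges,
                         apply_indirect_path_filter)
from .splitting import evaluate_all_nodes, split_nodes
from .reconstruct import Layout, embed_and_refine, spectral_embed
from .metrics import (knn_overlap, procrustes_disparity, split_jaccard,
                      split_overlap)

logger = logging.getLogger("minipath")

__all__ = [
    "ExperimentConfig",
    "SWEEP_AMPLITUDES",
    "SWEEP_SPREADS",
    "FUSED_FRACTIONS",
    "CROSSLINK_FRACTION",
    "weighted_quantile",
    "reconstruct_positions",
    "fused_node_cell",
    "fused_node_sweep",
    "crosslink_recon_cell",
    "crosslink_recon_sweep",
    "run_simulation_experiment",
    "run_experimental_chain",
]

#: Default (amplitude, spread) sweep grid.
SWEEP_AMPLITUDES: tuple[float, ...] = (1.0, 10.0, 100.0)
SWEEP_SPREADS: tuple[float, ...] = (20.0, 50.0, 100.0)
#: Fused-node event fractions pooled in the node-splitting sweep.
FUSED_FRACTIONS: tuple[float, ...] = (0.01, 0.05, 0.20)
#: Crosslink weight fraction used in the reconstruction-rescue sweep.
CROSSLINK_FRACTION: float = 0.20
#: Largest-component share below which a dataset is not reconstructed.
MIN_COMPONENT_FRACTION: float = 0.8


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Weighted lower quantile with linear interpolation.

    With unit weights this matches ``np.quantile`` up to the placement of the
    interpolation knots (midpoint convention); used to estimate a population
    quantile from stratified subsamples with inverse-sampling weights.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(values) == 0:
        raise ValueError("empty values")
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights) - 0.5 * weights
    cum /= weights.sum()
    return float(np.interp(q, cum, values))


# ---------------------------------------------------------------------------
# Reconstruction wrapper
# ---------------------------------------------------------------------------

def reconstruct_positions(g: BipartiteGraph, a: float, sigma: float,
                          refine_iterations: int = 60
                          ) -> tuple[Layout, float]:
    """Largest component -> spectral embed -> Poisson-ML refinement.

    Uses the likelihood-selected spectral plane (see
    :func:`minipath.reconstruct.embed_and_refine`).  Returns the refined
    layout and the largest-component node fraction; raises if the fraction
    is below the 80% reconstructability rule.
    """
    g_lc, frac = largest_component(g)
    if frac < MIN_COMPONENT_FRACTION:
        raise ValueError(
            f"largest component holds {frac:.1%} of nodes (< 80%); "
            "dataset flagged non-reconstructable")
    if refine_iterations > 0:
        layout, _ = embed_and_refine(g_lc, a=a, sigma=sigma,
                                     iterations=refine_iterations)
    else:
        layout = spectral_embed(g_lc)
    return layout, frac


# ---------------------------------------------------------------------------
# Fused-node sweep (normalized cuts + split accuracy)
# ---------------------------------------------------------------------------

def fused_node_cell(a: float, sigma: float, fraction: float,
                    seed: int | np.random.SeedSequence,
                    n_nodes: int = DEFAULT_N_NODES,
                    mask: tuple[int, int] | np.ndarray | None = None,
                    max_fused_eval: int = 100,
                    max_normal_eval: int = 100,
                    min_degree: int = 4) -> dict:
    """One sweep cell: simulate, fuse, evaluate ncuts, split at matched cutoff.

    Normalized cuts are evaluated on all ledgered fused nodes up to
    ``max_fused_eval`` plus ``max_normal_eval`` sampled unaltered nodes; the
    matched quantile cutoff (q = injected fraction) is estimated from the
    evaluated values with inverse-sampling weights per stratum.  Split
    partitions of fused nodes under the cutoff are scored with the best-match
    overlap against the ledgered pre-fusion neighbor sets.
    """
    if mask is None:
        mask = elliptical_mask()
    seq = (np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer))
           else seed)
    s_scene, s_sim, s_inj, s_sample = seq.spawn(4)
    scene = place_nodes(mask, n_nodes, 0.5, np.random.default_rng(s_scene))
    params = SimParams(a=a, sigma=sigma)
    g0 = simulate_graph(scene, params, np.random.default_rng(s_sim))
    g, ledger = inject_fused_nodes(g0, fraction, np.random.default_rng(s_inj))

    rng = np.random.default_rng(s_sample)
    fused_ids = [f.fused_id for f in ledger.fusions]
    normal_ids = [n for n in g.nodes() if n not in set(fused_ids)]
    f_sample = (list(rng.choice(fused_ids, max_fused_eval, replace=False))
                if len(fused_ids) > max_fused_eval else fused_ids)
    n_sample = (list(rng.choice(normal_ids, max_normal_eval, replace=False))
                if len(normal_ids) > max_normal_eval else normal_ids)
    cuts = evaluate_all_nodes(g, nodes=f_sample + n_sample,
                              min_degree=min_degree)

    def stratum(sample: list[str], population: int) -> tuple[np.ndarray, float]:
        vals = np.array([cuts[n].ncut for n in sample
                         if cuts[n].status == "evaluated"])
        weight = population / len(sample) if sample else 0.0
        return vals, weight

    fused_ncuts, w_f = stratum(f_sample, len(fused_ids))
    normal_ncuts, w_n = stratum(n_sample, len(normal_ids))

    # matched cutoff: q = injected fraction, over evaluated nodes
    all_vals = np.concatenate([fused_ncuts, normal_ncuts])
    all_w = np.concatenate([np.full(len(fused_ncuts), w_f),
                            np.full(len(normal_ncuts), w_n)])
    cutoff = (weighted_quantile(all_vals, all_w, fraction)
              if len(all_vals) else np.nan)

    id_map = {}
    for f in ledger.fusions:
        id_map[f.original_1] = f.fused_id
        id_map[f.original_2] = f.fused_id
    overlaps = []
    jaccards = []
    split_fused = []
    for f in ledger.fusions:
        if f.fused_id not in cuts:
            continue
        c = cuts[f.fused_id]
        if c.status != "evaluated" or not (c.ncut < cutoff):
            continue
        truth = ([id_map.get(i, i) for i in f.neighbors_1],
                 [id_map.get(i, i) for i in f.neighbors_2])
        overlaps.append(split_overlap((c.part1, c.part2), truth))
        jaccards.append(split_jaccard((c.part1, c.part2), truth))
        split_fused.append(f.fused_id)

    statuses = [cuts[n].status for n in f_sample + n_sample]
    result = {
        "a": a, "sigma": sigma, "fraction": fraction,
        "n_fused_total": len(fused_ids), "n_normal_total": len(normal_ids),
        "fused_ncuts": fused_ncuts, "normal_ncuts": normal_ncuts,
        "fused_weight": w_f, "normal_weight": w_n,
        "matched_cutoff": cutoff,
        "split_overlaps": np.array(overlaps),
        "split_jaccards": np.array(jaccards),
        "n_split_fused": len(split_fused),
        "n_unevaluable": sum(s == "unevaluable_components" for s in statuses),
        "n_too_few": sum(s == "too_few_neighbors" for s in statuses),
        "n_evaluated": sum(s == "evaluated" for s in statuses),
    }
    logger.info("fused cell a=%g sigma=%g frac=%g: %d fused / %d normal ncuts, "
                "%d splits, cutoff %.4f", a, sigma, fraction,
                len(fused_ncuts), len(normal_ncuts), len(overlaps),
                cutoff if np.isfinite(cutoff) else -1)
    return result


def fused_node_sweep(seed: int,
                     amplitudes: Sequence[float] = SWEEP_AMPLITUDES,
                     spreads: Sequence[float] = SWEEP_SPREADS,
                     fractions: Sequence[float] = FUSED_FRACTIONS,
                     n_nodes: int = DEFAULT_N_NODES,
                     mask: tuple[int, int] | np.ndarray | None = None,
                     max_fused_eval: int = 100,
                     max_normal_eval: int = 100) -> list[dict]:
    """Full fused-node sweep over the (amplitude, spread, fraction) grid."""
    cells = [(a, s, f) for a in amplitudes for s in spreads for f in fractions]
    seeds = np.random.SeedSequence(seed).spawn(len(cells))
    return [fused_node_cell(a, s, f, child, n_nodes=n_nodes, mask=mask,
                            max_fused_eval=max_fused_eval,
                            max_normal_eval=max_normal_eval)
            for (a, s, f), child in zip(cells, seeds)]


def pooled_ncut_means(results: Iterable[dict]) -> dict[str, float]:
    """Node-level pooled mean ncut of fused and of unaltered nodes."""
    fused = np.concatenate([r["fused_ncuts"] for r in results])
    normal = np.concatenate([r["normal_ncuts"] for r in results])
    return {"fused_mean_ncut": float(fused.mean()),
            "normal_mean_ncut": float(normal.mean()),
            "fused_sd": float(fused.std()), "normal_sd": float(normal.std()),
            "n_fused": len(fused), "n_normal": len(normal)}


def pooled_split_overlap(results: Iterable[dict],
                         variant: str = "best_match") -> float:
    """Mean split accuracy over all split ledgered fusions in a sweep.

    ``best_match`` is the contained-fraction score; ``jaccard`` the symmetric
    Jaccard variant (both are recorded per cell).
    """
    key = "split_overlaps" if variant == "best_match" else "split_jaccards"
    overlaps = np.concatenate([r[key] for r in results])
    return float(overlaps.mean())


# ---------------------------------------------------------------------------
# Crosslink sweep (indirect paths + reconstruction rescue)
# ---------------------------------------------------------------------------

def crosslink_recon_cell(a: float, sigma: float, fraction: float,
                         quantile: float,
                         seed: int | np.random.SeedSequence,
                         n_nodes: int = DEFAULT_N_NODES,
                         mask: tuple[int, int] | np.ndarray | None = None,
                         refine_iterations: int = 60,
                         score_method: str = "auto") -> dict:
    """One cell of the crosslink sweep.

    Reconstructs the error-free graph, the graph with injected crosslinks,
    and the corrected graph (edges under the ``quantile`` cutoff of the
    indirect-path distribution removed), and reports Procrustes disparities
    against the true coordinates plus the score-separation statistics.
    Edges of the corrupted graph carrying no pre-injection weight are the
    ledgered pure crosslinks; edges that existed before injection count as
    original.
    """
    if mask is None:
        mask = elliptical_mask()
    seq = (np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer))
           else seed)
    s_scene, s_sim, s_inj = seq.spawn(3)
    scene = place_nodes(mask, n_nodes, 0.5, np.random.default_rng(s_scene))
    params = SimParams(a=a, sigma=sigma)
    g0 = simulate_graph(scene, params, np.random.default_rng(s_sim))

    ids = sorted(scene.ids)
    truth = Layout(ids=ids, xy=scene.layout_array(ids),
                   provenance="ground_truth")

    record: dict = {"a": a, "sigma": sigma, "fraction": fraction,
                    "quantile": quantile}
    layout0, frac0 = reconstruct_positions(g0, a, sigma, refine_iterations)
    record["baseline_disparity"] = procrustes_disparity(truth, layout0)
    record["baseline_component_fraction"] = frac0

    if fraction > 0:
        g_err, _ledger = inject_spurious_crosslinks(
            g0, fraction, np.random.default_rng(s_inj))
        scores = indirect_path_values(g_err, method=score_method)
        # classify scored edges against the pre-injection graph
        rows = np.array([g_err.u_index[u] for u in scores.u])
        cols = np.array([g_err.v_index[v] for v in scores.v])
        orig_w = np.asarray(g0.matrix[rows, cols]).ravel()
        spurious_mask = orig_w == 0
        record["spurious_mean_wi3"] = float(scores.wi3[spurious_mask].mean())
        record["original_mean_wi3"] = float(scores.wi3[~spurious_mask].mean())
        record["n_spurious_edges"] = int(spurious_mask.sum())
        record["n_original_edges"] = int((~spurious_mask).sum())

        layout_err, _ = reconstruct_positions(g_err, a, sigma,
                                              refine_iterations)
        record["uncorrected_disparity"] = procrustes_disparity(truth, layout_err)

        threshold = quantile_cutoff(scores, quantile)
        g_corr, removed = filter_edges(g_err, scores, threshold, mode="below")
        record["n_removed"] = len(removed)
        rem_rows = {(u, v) for u, v, _ in removed}
        sp_pairs = {(u, v) for u, v, m in zip(scores.u, scores.v, spurious_mask) if m}
        record["edge_tp_fraction"] = (len(rem_rows & sp_pairs) / len(sp_pairs)
                                      if sp_pairs else 0.0)
        orig_pairs_n = int((~spurious_mask).sum())
        record["edge_fp_fraction"] = ((len(rem_rows) - len(rem_rows & sp_pairs))
                                      / orig_pairs_n if orig_pairs_n else 0.0)
        layout_corr, frac_c = reconstruct_positions(g_corr, a, sigma,
                                                    refine_iterations)
        record["corrected_disparity"] = procrustes_disparity(truth, layout_corr)
        record["corrected_component_fraction"] = frac_c
    logger.info("crosslink cell a=%g sigma=%g: baseline %.4f uncorrected %s "
                "corrected %s", a, sigma, record["baseline_disparity"],
                record.get("uncorrected_disparity"),
                record.get("corrected_disparity"))
    return record


def crosslink_recon_sweep(seed: int,
                          amplitudes: Sequence[float] = SWEEP_AMPLITUDES,
                          spreads: Sequence[float] = SWEEP_SPREADS,
                          fraction: float = CROSSLINK_FRACTION,
                          quantile: float | None = None,
                          n_nodes: int = DEFAULT_N_NODES,
                          mask: tuple[int, int] | np.ndarray | None = None,
                          refine_iterations: int = 60) -> list[dict]:
    """Crosslink sweep; the default cutoff quantile equals the error fraction."""
    if quantile is None:
        quantile = fraction
    cells = [(a, s) for a in amplitudes for s in spreads]
    seeds = np.random.SeedSequence(seed).spawn(len(cells))
    return [crosslink_recon_cell(a, s, fraction, quantile, child,
                                 n_nodes=n_nodes, mask=mask,
                                 refine_iterations=refine_iterations)
            for (a, s), child in zip(cells, seeds)]


# ---------------------------------------------------------------------------
# Generic config-driven experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Declarative sweep description (JSON or YAML)."""

    n_nodes: int = DEFAULT_N_NODES
    mask: tuple[int, int] = DEFAULT_MASK
    type_fraction: float = 0.5
    amplitudes: tuple[float, ...] = SWEEP_AMPLITUDES
    spreads: tuple[float, ...] = SWEEP_SPREADS
    error_type: Literal["none", "crosslink", "fusion", "bias"] = "none"
    fractions: tuple[float, ...] = (0.0,)
    quantiles: tuple[float, ...] = (0.0,)
    bias_factor: float = 2.0
    refine_iterations: int = 30
    knn_k: int = 15
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("amplitudes", "spreads", "fractions", "quantiles"):
            if not len(getattr(self, name)):
                raise ValueError(f"{name} grid must be nonempty")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "mask" in data:
            data["mask"] = tuple(data["mask"])
        for name in ("amplitudes", "spreads", "fractions", "quantiles"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)       # output location is not identity
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_simulation_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run every (amplitude, spread, fraction, quantile) cell of the config.

    Per cell: simulate -> inject -> correct at the quantile cutoff -> check
    the 80%-connectivity rule -> reconstruct -> evaluate.  Cells that fail
    connectivity are emitted with ``skipped_reason`` set.  Writes
    ``results.tsv`` and ``config.json`` (with hash and seed) to ``out_dir``
    when configured; re-running a config reproduces the files byte for byte.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    cells = [(a, s, f, q) for a in cfg.amplitudes for s in cfg.spreads
             for f in cfg.fractions for q in cfg.quantiles]
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(cells))
    rows = []
    for (a, sigma, fraction, quantile), child in zip(cells, seeds):
        row = {"a": a, "sigma": sigma, "fraction": fraction,
               "quantile": quantile, "error_type": cfg.error_type,
               "seed": cfg.seed, "config_hash": cfg.config_hash(),
               "skipped_reason": ""}
        try:
            row.update(_experiment_cell(cfg, a, sigma, fraction, quantile, child))
        except ValueError as exc:
            row["skipped_reason"] = str(exc)
            logger.info("cell a=%g sigma=%g skipped: %s", a, sigma, exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        df.to_csv(out_dir / "results.tsv", sep="\t", index=False,
                  float_format="%.10g")
        (out_dir / "config.json").write_text(json.dumps(
            {"config": asdict(cfg), "hash": cfg.config_hash()},
            indent=2, default=str) + "\n")
    return df


def _experiment_cell(cfg: ExperimentConfig, a: float, sigma: float,
                     fraction: float, quantile: float,
                     seq: np.random.SeedSequence) -> dict:
    s_scene, s_sim, s_inj = seq.spawn(3)
    scene = place_nodes(cfg.mask, cfg.n_nodes, cfg.type_fraction,
                        np.random.default_rng(s_scene))
    params = SimParams(a=a, sigma=sigma)
    ids = sorted(scene.ids)
    truth = Layout(ids=ids, xy=scene.layout_array(ids),
                   provenance="ground_truth")
    out: dict = {}
    if cfg.error_type == "bias":
        g, _ = inject_reactivity_bias(scene, params, fraction,
                                      cfg.bias_factor,
                                      np.random.default_rng(s_sim))
    else:
        g = simulate_graph(scene, params, np.random.default_rng(s_sim))
        if cfg.error_type == "crosslink" and fraction > 0:
            g, _ = inject_spurious_crosslinks(
                g, fraction, np.random.default_rng(s_inj))
            if quantile > 0:
                g, removed, _sc = apply_indirect_path_filter(
                    g, quantile=quantile, mode="below")
                out["n_removed_edges"] = len(removed)
        elif cfg.error_type == "fusion" and fraction > 0:
            g, _ = inject_fused_nodes(g, fraction,
                                      np.random.default_rng(s_inj))
            if quantile > 0:
                cuts = evaluate_all_nodes(g)
                vals = np.array(list(cuts.ncut_values().values()))
                if len(vals):
                    cut = float(np.quantile(vals, quantile))
                    g, split_map = split_nodes(g, cuts, cut)
                    out["n_split_nodes"] = len(split_map)
    layout, frac = reconstruct_positions(g, a, sigma, cfg.refine_iterations)
    out["component_fraction"] = frac
    common = sorted(set(truth.ids) & set(layout.ids))
    out["n_nodes_evaluated"] = len(common)
    out["procrustes_disparity"] = procrustes_disparity(truth, layout)
    if len(common) > cfg.knn_k:
        out["knn_overlap"] = knn_overlap(truth, layout, k=cfg.knn_k)
    return out


# ---------------------------------------------------------------------------
# Experimental-data chain
# ---------------------------------------------------------------------------

def run_experimental_chain(uei: str | Path | UEITable,
                           filter_spec: dict,
                           out_dir: str | Path | None = None,
                           score_method: str = "auto") -> dict:
    """UEI table -> chosen filter -> <2-product filter -> largest component.

    ``filter_spec`` is ``{"read_count": k}`` or ``{"indirect_path": c}``
    (absolute cutoff ``c``; edges with w_i3 < c are removed).  Returns the
    per-stage accounting: surviving UEIs, edges, and beacon/target polonies.
    """
    table = uei if isinstance(uei, UEITable) else load_uei_table(uei)
    if len(filter_spec) != 1:
        raise ValueError("filter_spec must name exactly one filter")
    (kind, value), = filter_spec.items()
    summary: dict = {"filter": kind, "value": value,
                     "input_ueis": len(table)}
    if kind == "read_count":
        table = read_count_filter(table, int(value))
        g = aggregate(table)
    elif kind == "indirect_path":
        g = aggregate(table)
        g, removed, _scores = apply_indirect_path_filter(
            g, cutoff=float(value), mode="below", method=score_method)
        summary["removed_edges"] = len(removed)
    else:
        raise ValueError(f"unknown filter {kind!r}; "
                         "expected read_count or indirect_path")
    logger.info("after %s filter: %s", kind, g.metadata())
    g = iterative_low_product_filter(g)
    logger.info("after <2-product filter: %s", g.metadata())
    g, frac = largest_component(g)
    logger.info("largest component: %s (fraction %.3f)", g.metadata(), frac)
    summary.update(g.metadata())
    summary["component_fraction"] = frac
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        g.to_edge_tsv(out_dir / "filtered_edges.tsv")
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2) + "\n")
    return summary
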