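# Methods

## Data model

The substrate is an undirected weighted bipartite graph `G = (U, V, E, w)`:
`U` beacon-type polonies, `V` target-type polonies, and integer weights
`w(u, v) ≥ 1` equal to the number of distinct UEIs (unique event
identifiers) sequenced for the pair.  Experimental input arrives as a UEI
table (one row per concatemer: beacon id, target id, UEI barcode, read
count); aggregation counts distinct UEIs per pair — read counts are kept for
filtering but never summed into edge weights.  Node ids are opaque strings
and bipartition membership is stored per node, never inferred from id
prefixes.  Matrix exports fix rows = lexicographically sorted `U`, columns =
sorted `V`.

## Simulator

Polony interaction in a hydrogel is diffusion-limited; the simulator draws
every opposite-type pair independently as

    w(i, j) ~ Poisson( a · exp(−|x_i − x_j|² / σ²) )

with amplitude `a` (reactivity × sequencing depth) and spread `σ` in pixels,
the analogue of the diffusion length `L_diff = sqrt(8 d D t)` (σ may be
given directly or derived from `D`, `t`, `d`; both must agree to 1e-9
relative).  Scenes place nodes uniformly in a mask, each node independently
typed beacon with probability 0.5.

Standard study region: ~4,000 nodes in a ~40,000 px² region of a 200 × 450
px grid (density ≈ 0.1 node/px²).  The region used by the sweeps is an
ellipse of that area with the grid's aspect ratio — a synthetic stand-in for
a tissue-like irregular shape; arbitrary boolean masks are supported.  Pair
enumeration is exact O(|U|·|V|) at this scale; an optional distance cutoff
(means beyond it set to 0) exists as a speed knob for much larger scenes and
is off everywhere in the shipped studies.

Three artifacts are injected with full ground-truth ledgers:

* **crosslinks** — `round(fraction · Σw)` unit-weight events, each joining an
  independently uniform U node and V node; existing pairs are incremented
  and still ledgered (the ledger aggregates added weight per pair).  The
  fraction is measured against total edge weight.
* **fusions** — `round(fraction · |U ∪ V|)` events; each draws an unordered
  pair uniformly from all not-yet-fused same-type pairs (so a side is chosen
  with probability proportional to its eligible-pair count).  The fused node
  inherits per-neighbor summed weights; the ledger records both constituents
  and their pre-fusion neighbor sets, which later anchors split-accuracy
  scoring.
* **reactivity bias** — the Poisson mean of every pair is multiplied by a
  per-node factor (default 2.0; the magnitude is a free parameter of the
  model) once per biased endpoint.  With bias fraction 0 and the same seed
  the draw reproduces the plain simulation bit for bit.

What the generator emulates: diffusion-scale Gaussian adjacency, two seed
types, Poisson sampling noise, and the three artifact classes, at realistic
density.  What it does not: irregular tissue boundaries (ellipse stand-in),
spatially varying polony density, PCR amplification chemistry, barcode
sequence errors (fusions are injected directly rather than via barcode
collision), or read-depth structure within a UEI.  Passing tests therefore
demonstrate correctness of the graph algorithms under the generative model,
not robustness to every real-data pathology.

## Crosslink filter

For an edge (x, y), the indirect-path value

    w_i3(x, y) = Σ_{a ∈ V \ {y}} Σ_{b ∈ U \ {x}} w(x,a) · w(a,b) · w(b,y)

is the weighted number of 3-step walks between the endpoints avoiding both.
Three implementations agree integer-exactly and are cross-checked against
each other in the tests:

* `reference`: the literal quadruple loop (oracle; small graphs only);
* `dense`: `A Aᵀ A` with closed-form exclusion — walks through a = y
  contribute `w(x,y)·Σ_b w(b,y)²`, walks through b = x contribute
  `w(x,y)·Σ_a w(x,a)²`, and their overlap `w(x,y)³` is added back once.
  Exact in float64 at these weight ranges (all values < 2^53);
* `sparse`: per-edge sparse dot of the two-step matrix `A Aᵀ` rows against
  adjacency columns, numba-parallel; each edge is scored independently, so
  the result is thread-count invariant.

Removal is single-pass by default: score once, remove every edge under the
cutoff simultaneously (an iterative re-score mode exists, off by default).
Cutoffs are either absolute ("keep if `w_i3 ≥ c`", the convention used with
integer cutoffs 1 and 2 on experimental data; an `at_or_below` flag covers
the closed-boundary reading) or a lower quantile of the score distribution
(linear-interpolation definition).  The working guideline is quantile
cutoff = expected error fraction.

## Node splitter

For a center `a`, the neighbor graph `G_a` has nodes `S_a` (a's neighbors)
and two-step weights `w_i2(x, y) = Σ_{b ≠ a} w(b,x) w(b,y)` with `b` running
over a's own side — paths through `a` itself are excluded, which subtracts a
rank-one term and lets all centers share one Gram matrix (`Aᵀ A` or
`A Aᵀ`).  The diagonal of `w_i2` is strictly positive by construction and is
zeroed before partitioning (self-loops carry no cut information).

Evaluation rules: fewer than 4 neighbors (`min_degree`, counting distinct
neighbors) → not considered; exactly two connected components → that
bipartition with ncut 0.0; more than two components → unevaluable (data too
sparse to distinguish a fusion from disconnection); otherwise a two-way
partition scored by the Shi–Malik normalized cut with ordered-pair assoc
sums (`assoc(S_i) = Σ_{u∈S_i} Σ_{t∈S_a} w_i2(u,t)`, so within-part weight
counts once per endpoint; ncut ∈ [0, 2]).  Connectivity is found by dense
BFS matvecs with an early exit past three components.

Partitioning is exact for `|S_a| ≤ 12` (enumeration of all bipartitions) and
spectral above: the Fiedler vector of the symmetrically normalized affinity,
mapped back through `D^{-1/2}`, orders the nodes (ties broken by node id;
fixed Lanczos start vector, so the result is deterministic), and the
minimum-ncut prefix split along that ordering is taken.  The sweep cut
evaluates true ncut values, so the spectral route can never return a value
below the exact minimum, and on two-component graphs the component rule fires
before either.

Splitting replaces each node with ncut below the cutoff by two nodes
(`<id>.1`, `<id>.2`) inheriting the edges to either partition; if both
endpoints of an edge were split the edge is deleted.  All decisions are
taken on the pre-split cut table (single pass).  Quantile cutoffs for
splitting are computed over evaluated nodes only.  When both corrections are
requested, crosslink filtering runs first — spurious edges corrupt neighbor
subgraphs and would inflate false fusion calls.  Downstream joins to ground
truth must use the returned split map, not id parsing.

## Reconstruction

Reconstruction is the measuring instrument for the error/correction
experiments: a spectral maximum-likelihood embedding, fully specified here so
results are reproducible.

1. **Spectral initialization** — on the largest connected component (the
   pipeline refuses datasets whose largest component holds < 80% of nodes),
   take the symmetric degree-normalized adjacency of the full node set; the
   coordinates are eigenvectors of the largest nontrivial eigenvalues,
   de-normalized by `D^{-1/2}` and scaled by their eigenvalues.  Signs are
   fixed by the first node, so the embedding is deterministic.  In elongated
   regions the 3rd eigenvector can be a higher harmonic of the long axis
   rather than the short-axis mode, which initializes a folded "horseshoe"
   that refinement cannot reliably unfold at small σ (the Gaussian kernel
   carries no long-range forces).  The pipeline therefore probes the three
   planes spanned by the top-4 nontrivial eigenvectors with a short
   refinement each and keeps the one with the highest Poisson
   log-likelihood — a selection that needs no ground truth — before
   refining to the full budget (`embed_and_refine`).  The plain 2nd/3rd
   eigenvector embedding remains available as `spectral_embed`.
2. **Poisson-ML refinement** — joint ascent of the Poisson log-likelihood of
   all observed weights and all zero counts of absent opposite-type pairs
   under the simulator's mean model, at the true (or profiled) `a`, `σ`.
   The unit-free spectral layout is first scaled onto the likelihood's
   length unit by a 25-point log-grid search.  Ascent uses Barzilai–Borwein
   steps safeguarded by halving, so the objective trace is monotone
   non-decreasing; the stiff mode is the global "uncurling" of the bent
   spectral solution at small σ, which converges in ≈ 80 BB iterations where
   fixed-step ascent needs several hundred.  Zero-count pairs are evaluated
   exactly (dense) at the shipped problem sizes.

When `a`/`σ` are unknown, they are profiled on a fixed layout: `a` has the
closed form `Σw / Σ exp(−d²/σ²)` and `σ` is maximized over a log grid.

## Evaluation metrics

* **Procrustes disparity** (global): both layouts centered, unit-scaled,
  optimally aligned by an orthogonal transform *including reflections*
  (graph reconstructions have arbitrary chirality); the residual sum of
  squares is reported.  0 ≡ identical up to similarity.
* **k-NN overlap** (local, default k = 15): mean fraction of shared
  k-nearest neighbors between the two layouts, Euclidean, self excluded; a
  random layout scores ≈ k/(n−1).
* **Split accuracy**: recovered partitions vs the ledgered pre-fusion
  neighbor sets (ids mapped through any later fusions).  Two variants are
  computed everywhere: the best-match contained fraction
  `(max_t |S_1∩t|/|S_1| + max_t |S_2∩t|/|S_2|)/2`, and a symmetric Jaccard
  score (best pairing of parts to truth sets, mean of `|∩|/|∪|`).  The
  contained fraction ignores truth members missing from a part, so it runs
  systematically higher (≈ 0.95 vs ≈ 0.80 on the standard sweep); the
  Jaccard is the headline number reported by the acceptance script.
* **Detection rates**: an edge removed counts as true positive iff its pair
  had no pre-injection weight (pure spurious); pairs that existed and were
  merely incremented count as original.  Node TP/FP analogously against the
  fusion ledger; unevaluable nodes are excluded from the denominators and
  reported separately.

## Study conditions and problem sizes

The standard sweeps — the package's own choice of study size — use
amplitudes {1, 10, 100} × spreads {20, 50, 100} at ~4,000 nodes, fused-node
fractions {1%, 5%, 20%} and a crosslink fraction of 20% with the matched
quantile cutoff 0.2.  Per fused-node cell, normalized cuts are evaluated on
all ledgered fused nodes up to a cap of 150 (acceptance script; 60 in the
test suite) plus an equal sample of unaltered nodes; pooled means and
matched quantile cutoffs are estimated with inverse-sampling weights per
stratum (weighted linear-interpolation quantile, midpoint convention).
Sampling error of the pooled means at these caps is below 0.01.

On this study the sweeps reproduce the qualitative findings: fused nodes cut
far below unaltered nodes (pooled ≈ 0.55 vs ≈ 0.74; the fused mean rises
steeply with the injected fraction, from ≈ 0.44 at 1% to ≈ 0.65 at 20%, so
pooled values depend on the fraction mix), spurious crosslinks score below
original edges in every cell, error-free baselines reconstruct essentially
perfectly (mean disparity ≈ 0.001), 20% crosslinks distort reconstructions
by two orders of magnitude or more (mean disparity ≈ 0.24; the small-spread
cells converge to heavily distorted optima at ≈ 0.4–0.65 while large-spread
cells partially resist the corruption), and the matched-quantile correction
rescues them in at least 8 of 9 cells.  How badly an uncorrected corrupted
graph reconstructs is a property of the reconstruction solver, so absolute
corrupted-disparity levels are comparable across runs of this package but
not across different embedding tools.

## Numerical choices and degenerate inputs

* Integer arithmetic end to end for scores (int64; dense route exact in
  float64 well past the weight ranges used).
* Ties: largest-component ties broken by smallest lexicographic node id;
  Fiedler-ordering ties by node id; quantiles by linear interpolation.
* `iterative_low_product_filter` removes all sub-threshold nodes per round
  (fixed point independent of order); "products" are total incident UEIs,
  not edge count, since each UEI is one sequenced concatemer.
* Empty graphs: largest component of an empty graph is itself with fraction
  defined as 0; amplitude 0 is allowed and yields an edgeless graph.
* All randomness flows from one integer seed through `SeedSequence` spawns
  (one child per sweep cell, one per stage within a cell), so any cell can
  be reproduced in isolation and injections are independent of iteration
  order.

## Known limitations

* The reconstructor is a documented stand-in pinned to this package, not a
  re-implementation of any external embedding tool; absolute disparity
  levels on corrupted graphs depend on it, so those quantities are
  reproducible here but only approximately comparable across tools.
* Length-5/7 indirect paths, degree-normalized scores, k-way splits and
  non-bipartite (e.g. chromatin-contact) graphs are out of scope.
* Crosslinks landing on already-connected nearby pairs are inherently
  undetectable by topology; the filter's TP rate is bounded well below 1 by
  construction, matching the behavior it is meant to correct.
* The <2-product filter and largest-component selection are intended for
  experimental UEI data; simulated sweeps skip them (simulation produces no
  sequencing-error singletons).
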