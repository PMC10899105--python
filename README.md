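# minipath

Graph-based error correction for DNA-microscopy adjacency data.

DNA microscopy reconstructs the spatial layout of molecules from sequencing
alone: barcoded transcripts are amplified in place into polonies, overlapping
polonies form sequenced concatemers, and each concatemer carries a unique
event identifier (UEI).  The data is a weighted bipartite graph — one node
per polony (two seed types, "beacons" and "targets"), one edge per observed
polony pair, edge weight = number of distinct UEIs — from which 2D
coordinates are inferred.  Two experimental artifacts corrupt this graph and
distort reconstructions:

* **spurious crosslinks** — edges formed between arbitrary, typically
  distant polonies (e.g. chimeric PCR after lysis);
* **fused nodes** — one node erroneously representing two polonies (barcode
  collision or over-merged barcodes), inheriting both edge sets.

`minipath` ("minimum indirect path") detects both by exploiting the rule
that spatially close polonies share many short indirect connections:

* an edge (x, y) is scored by its **indirect-path value**

  $w_{i3}(x,y)=\sum_{a\in V\setminus\{y\}}\;\sum_{b\in U\setminus\{x\}} w(x,a)\,w(a,b)\,w(b,y),$

  the weighted count of length-3 paths avoiding the edge itself.  Genuine
  edges score high; crosslinks between distant polonies score near zero and
  are removed below an absolute or lower-quantile cutoff.

* a node `a` is scored by partitioning its neighbor subgraph $G_a$ (nodes
  $S_a$, weights $w_{i2}(x,y)=\sum_{b\neq a} w(b,x)\,w(b,y)$) in two and
  computing the **normalized cut**

  $\mathrm{ncut}(S_1,S_2)=\frac{\mathrm{cut}(S_1,S_2)}{\mathrm{assoc}(S_1)}+\frac{\mathrm{cut}(S_1,S_2)}{\mathrm{assoc}(S_2)}.$

  A fused node's neighbors form two nearly disconnected groups, so its ncut
  is low; such nodes are split into two nodes inheriting the edges to either
  partition.

The package also ships everything needed to validate the corrections end to
end: a diffusion-based Poisson simulator
($w(i,j)\sim\mathrm{Poisson}(a\,e^{-|x_i-x_j|^2/\sigma^2})$) with injectors
for crosslinks, fusions and reactivity bias (each with a ground-truth
ledger); a spectral + Poisson-maximum-likelihood reconstructor; Procrustes /
k-NN / detection metrics; UEI-table filters for experimental data; and a
config-driven sweep runner with a thin `minipath` CLI.

## Worked example

```bash
python examples/correct_crosslinks.py
```

```text
clean graph: 16512 edges, total weight 62399
with crosslinks: 21397 edges (+6240 spurious weight)
removed 2140 edges at w_i3 < 12337
true-positive rate 0.44 (fraction of spurious edges caught), false-positive rate 0.0003 (fraction of real edges lost)
```

A 600-polony scene is simulated, spurious crosslinks worth 10% of the total
edge weight are injected, and edges under the 10%-quantile indirect-path
cutoff are removed (guideline: quantile cutoff = expected error fraction).
Here 44% of the injected crosslinks are caught while only 0.03% of genuine
edges are lost — crosslinks between nearby polonies are inherently
indistinguishable from real edges, which is why the true-positive rate sits
below 1 while the false-positive rate stays near 0.

The other examples follow the same pattern: `split_fused_nodes.py` (fused
ncut 0.27 vs 0.64 for unaltered nodes, split recovery Jaccard ≈ 0.95 on an
easy scene), `reconstruct_scene.py` (Procrustes disparity 0.0007, 15-NN
overlap 0.90), and `experimental_chain.py` (read-count vs indirect-path
filter on a UEI table).

From Python, the same workflow is:

```python
from minipath import (place_nodes, simulate_graph, SimParams,
                      inject_spurious_crosslinks, apply_indirect_path_filter)

scene = place_nodes(mask=(100, 150), n_nodes=600, seed=1)
g0 = simulate_graph(scene, SimParams(a=10, sigma=20), seed=2)
g, ledger = inject_spurious_crosslinks(g0, fraction=0.10, seed=3)
g_clean, removed, scores = apply_indirect_path_filter(g, quantile=0.10)
```

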