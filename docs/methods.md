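# Methods

This note documents the model, the defaults and why they were chosen, the
numerical corners, and what the synthetic benchmarks do and do not show.

## The co-embedding model

The object being laid out is a heterogeneous undirected graph with two node
types (cells, genes) and exactly two legal edge classes, all edges with
unit weight:

- **cell–cell**: each cell is joined to its `k = 20` nearest cells by
  Euclidean distance on the top principal components (default 500, clamped
  to `min(cells − 1, genes)`) of the log-normalized expression matrix.
  Directed kNN lists are symmetrized by union; mutuality is not required.
  Exact neighbor search is used up to 2000 cells, an NN-descent approximate
  index (pynndescent) above, both seeded.
- **cell–gene**: each gene of the current pass's gene set is joined to the
  `n = 10` cells with its highest normalized expression (ties broken by
  cell order in the matrix, which makes construction deterministic).

Gene–gene edges cannot be expressed in the container, and a validator
rejects malformed inputs on import.

The pass structure is fixed at four:

1. genes = 500 largest max-absolute-loading genes over the retained PCs;
2. –3. genes = up to 500 one-vs-rest DE genes of the previous pass's
   clusters with adjusted *P* < 0.5 **and** log2FC > 1.2 (both strict;
   if nothing passes, the PCA selection is reused with a warning);
4. genes = each cluster's top 20 upregulated markers, where the gene at
   within-cluster rank *i* connects to `p = 5 − ceil(i/10)` of its own
   cluster's cells (its top-`p` by expression within the cluster — the
   pass-1–3 rule restricted to the cluster).

Cell coordinates and clusters are taken from pass 3. Pass 4 exists only to
position the markers; its cell coordinates are never reported.

The `P < 0.5` default follows the published workflow this package
implements; 0.05 is the conventional significance cutoff and both are
plain config parameters (`p_adj_max`).

## Preprocessing

Cells expressing fewer than 30% of the mean expressed-gene count are
removed (strict inequality; "expressed" means count > 0), then genes
detected in fewer than 3 cells. Counts are scaled per cell to the median
pre-normalization total and log1p-transformed. Highly variable genes
(default 500) are ranked by Cell-Ranger-flavor normalized dispersion —
dispersion of expm1 expression, z-scored within mean bins — computed on the
log-normalized matrix via scanpy. The HVG subset feeds PCA; DE and
gene-edge expression lookups use the full filtered matrix.

Note that the 30%-of-mean cell filter cannot empty a non-empty matrix (the
most complex cell always sits at or above 30% of the mean), so the
"empty after filtering" failure can only be triggered by empty input.

## Structure-preserving subsampling

Datasets above 5000 cells (configurable) are thinned before layout.
Preliminary communities come from Leiden modularity optimization on the
cell kNN graph (seeded, hence deterministic); each community of size `s` is
then sampled without replacement at proportion

    p(s) = p_l − exp(−s / k) (p_l − p_u),

defaults `p_l = 0.3`, `p_u = 0.9`, `k = 500`. The source method leaves
these unspecified; the defaults keep clusters of a few hundred cells
near-complete while thinning ten-thousand-cell clusters toward 30%,
bounding layout size without losing rare populations. Per-cluster counts
are round-half-away-from-zero of `p·s`, floored at one cell. Held-out
cells are assigned post hoc after pass 3: majority vote among the 20
nearest sampled cells in PC space (ties go to the single nearest
neighbor), with 2D coordinates set to the mean position of the same-label
neighbors. PC space is used for the query because held-out cells have no
layout coordinates of their own.

## Layout

The objective is attraction plus density,

    Σ_i ( Σ_j w_ij d(x_i, x_j)² + D_{x_i} ),

with `w_ij = 1` and `d` Euclidean. `D` ("density of the edges near x_i")
has no closed form; it is approximated by binning edge midpoints on a
fixed-resolution grid (64 bins per axis over the layout extent, Gaussian
kernel σ = 1 bin) and sampling the smoothed grid at each node. The
attraction term is reported per edge (each edge counted once).

Optimization is simulated annealing over the canonical five-stage schedule
(liquid 200 iterations / temperature 2000 / attraction 10, expansion
200/2000/2, cooldown 200/1000/1, crunch 50/250/1, simmer 100/250/0.5, with
per-stage damping); all stage parameters are a config block. Two backends
satisfy the same structural contract and either can be selected:

- `anneal` (default): a vectorized annealer. Each iteration every node
  evaluates three candidates — stay, a damped pull toward its neighbor
  centroid, a temperature-scaled Gaussian jump — and keeps the cheapest
  under its local energy (attraction to neighbors + grid density).
  Temperatures are rescaled to a fixed reference length √n and decay
  linearly within each stage, so the layout extent cannot run away. The
  density weight is balanced against the attraction term once per stage
  (not per iteration) to avoid a feedback loop between expansion and the
  adaptive weight. The centroid pull strengthens in crunch/simmer
  (0.7 vs 0.5 earlier), which is what tightens final clusters.
- `drl`: igraph's DrL implementation, driven by the same schedule and the
  same seed (igraph's RNG is replaced by a seeded Python RNG for the call).

During cutting stages (cooldown, crunch, simmer for the annealer; DrL has
its own internal schedule) the longest `0.3 × edge_cut` fraction of edges
is excluded from the attraction force, opening white space between weakly
connected regions. `edge_cut` defaults to 0.8 on the conventional 0–1
scale.

Backends are compared through properties (two bridged cliques must end up
internally tighter than they are to each other; objective decreases from a
random start; distance matrices equivariant to node relabeling), never
through coordinate equality. A single node is placed at the origin.

## Clustering the layout

DBSCAN runs on the cell coordinates of each pass's layout,
`min_samples = 20` (mirroring k). When `eps` is not given it is calibrated
from the sorted 20-NN-distance curve: the point of maximum distance to the
chord (the standard knee rule), computed on the positive segment of the
curve and floored at 1.2× the median k-distance. The floor matters because
an annealed layout can collapse a tight group onto coincident coordinates,
which puts a flat zero segment at the front of the curve and would
otherwise drag the knee to zero. Noise cells keep the −1 sentinel and
their coordinates; they are excluded from marker computation but carried
through to the outputs.

## Differential expression

One-vs-rest per cluster with the overestimated-variance t-test:

    t = (μ_g − μ_r) / sqrt(s_g²/n_g + s_r²/n_g),

i.e. **both** variance terms divided by the focal group's size `n_g`,
which inflates the rest group's standard error whenever the rest is larger
— a deliberately conservative variant. Degrees of freedom are
Welch–Satterthwaite with `n_g` in both terms; p-values are two-sided;
Benjamini–Hochberg runs across genes within one cluster-vs-rest comparison
(not across clusters — the family matches the per-cluster ranking
semantics). Variances are floored at 1e−9 so constant genes yield finite
statistics. log2 fold changes are computed on expm1-back-transformed mean
log expression with an epsilon of 1e−9, the convention of the standard
single-cell analysis stack. Clusters with fewer than two cells are skipped
with a warning.

## Gene placement

Per cluster, a KNN regressor (K = 5, clamped to the cluster size) is
trained from the cluster's cells' pass-4 coordinates to each pass-3
coordinate axis separately, then applied to the cluster's markers' pass-4
positions. Predictions are neighbor means, so a projected gene always lies
inside the bounding box of its cluster's cells. The same scheme projects
markers onto an external embedding (a user-supplied table or a seeded UMAP
of the PC scores); pass-4 coordinates remain the predictors there, which
is configurable. A gene that marks several clusters is placed once, under
its best (lowest) within-cluster rank.

## Spatial zonation

Given a genes × bins matrix of probabilistic mapping scores and bin
coordinates: each marker gene's score row is standardized across bins
(Stouffer combination requires z-scores; rows with zero variance carry no
positional signal and are dropped with a warning) and combined per bin as
`Σ_g z_gb / √G`. Binarization is a strict threshold; the threshold itself
is the caller's (manual) choice. Cluster correspondence between two assays
is the Pearson correlation of cluster-wise mean expression over a shared
gene panel, with zero-variance vectors recorded as missing. Coordinate
prediction fits one decision-tree regressor per coordinate axis (library
defaults: unlimited depth, minimum leaf 1, config-exposed) on
bootstrap-resampled bins, scoring RMSE on the out-of-bag bins, 50
replicates; empty out-of-bag draws are redrawn and logged.

## Synthetic data

`simulate_counts` draws negative-binomial counts (Gamma–Poisson mixture;
dispersion α in `var = μ + αμ²`) with per-gene base means uniform in
[0.5, 2], planted disjoint marker sets whose means are multiplied by
`2^log2fc` in their own cluster, and an optional rare cluster at a given
fraction. The standard benchmark conditions are 1000 cells × 2000 genes, 5
equal clusters, 50 markers per cluster at log2FC 2, dispersion 0.3 — a
strongly but not trivially separated regime (pass 1 typically misses a
cluster and the DE rewiring recovers it). `simulate_binmap` places bins on
an ellipse and gives each cluster's genes a Gaussian angular bump over one
contiguous arc plus iid noise. Both are pure functions of parameters and
seed.

What the generators do **not** emulate: batch effects, doublets, ambient
RNA, library-size confounding with cell type, or realistic gene–gene
correlation beyond the planted block structure. Passing the benchmarks
therefore demonstrates that the machinery is correct and stable, not that
the pipeline resolves subtle populations in real tissue.

## Problem sizes and determinism

Tests and the acceptance script run on 200–1000-cell simulations, chosen
so the full suite and the script each complete comfortably on one CPU.
Every stochastic component (simulation, PCA solver, approximate NN, layout
init and jumps, subsampling draws, bootstraps, UMAP) takes an explicit
seed; per-pass layout seeds are derived as `seed + 1000·pass`. With
subsampling disabled the whole pipeline is bit-reproducible, which is
asserted in the test suite.

## Known limitations

- The annealer's final layouts quantize tight groups to near-coincident
  points; fine within-cluster geometry is not meaningful (the DrL backend
  spreads clusters more smoothly).
- DBSCAN's automatic `eps` assumes the layout separates clusters by gaps
  large compared to within-cluster spacing; on weakly separated data it
  can merge or over-fragment, and `dbscan_eps` should be set explicitly.
- The four-pass count is fixed rather than convergence-tested; the
  per-pass ARI in `pass_log` is diagnostic only.
- Approximate-NN recall below ~90% (very high dimensions, tiny k) would
  degrade the graph silently; the exact backend is available at any size
  via `exact_nn=True`.
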