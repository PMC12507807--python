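# Methods

## The problem

Graph-based clustering of scRNA-seq data (Leiden/Louvain community
detection on a k-nearest-neighbor cell graph) requires a *resolution*
parameter, and the choice is usually made by eye. `scresolve` replaces
that choice with an explicit criterion: cluster the data at every
resolution in a grid, score each partition by its mean silhouette, and
select the resolution with the highest score.

## Silhouette scoring

For cell *i* in cluster *C*, with Euclidean distances *d* on the
embedding,

- a(i) = mean distance from *i* to the other members of *C*,
- b(i) = min over clusters *C' ≠ C* of the mean distance from *i* to
  members of *C'*,
- S(i) = (b(i) − a(i)) / max(a(i), b(i)),

and the partition score is S = (1/n) Σᵢ S(i) over **all** n cells.
Conventions (the standard ones for this statistic):

- cells in singleton clusters get S(i) = 0 and still count in the
  denominator;
- if max(a, b) = 0 (two clusters of mutually coincident points),
  S(i) = 0;
- partitions with fewer than 2 clusters have no silhouette; the sweep
  records them as *unscored* and excludes them from the optimization,
  so the degenerate all-one-cluster solution can never win (or lose)
  on an arbitrary constant.

Distances are taken in PCA space — the same space the neighbor graph is
built on — not on raw counts (where library depth dominates) and not in
a 2-D visualization layout. This is a documented assumption, exposed by
letting the caller pass any `Embedding`.

The production implementation accumulates per-cluster distance sums in
row chunks via exact coordinate-difference distances (`scipy`'s
`cdist`; no Gram-matrix shortcut, whose cancellation error is visible on
near-duplicate points). An independent O(n²) double-loop implementation
(`brute_force_silhouette`) shares no code with it and serves as the test
oracle; the suite requires agreement within 1e-9 on random instances.

## The sweep

- Grid: res_min 0.10 to res_max 1.50 in steps of 0.02, built by integer
  index (r = res_min + i·step) so floating-point accumulation cannot
  drop the endpoint. A step of 0.02 resolves two-decimal optima.
- Clustering: Leiden (RB-configuration modularity with the resolution
  parameter) by default; Louvain selectable. Labels are relabeled
  0..k−1 by descending cluster size. Per-grid-point seeds are derived
  as `config.seed + grid_index`, so removing one grid point does not
  shift the others' results.
- Selection: argmax of mean silhouette over scored entries; exact ties
  go to the **lowest** resolution (at equal quality, prefer fewer,
  coarser clusters).
- Large inputs: silhouette is O(n²), so an optional cluster-stratified
  subsample (proportional quotas, largest-remainder rounding, every
  cluster ≥ 1 cell, remainder ties to the lower cluster id) can be
  scored instead; on 5,000-cell simulations a 2,000-cell subsample
  moves the mean silhouette by < 0.05.

No monotonicity of k in the resolution is assumed (community detection
does not guarantee it); the suite only asserts that every recorded k ≥ 1
and every score lies in [−1, 1].

## Preprocessing

Defaults: discard cells with fewer than 200 or more than 2500 total
UMIs or with mitochondrial fraction above 10% (bounds are strict, so a
cell at exactly 200 UMIs and exactly 10% passes); mitochondrial genes
are taken from an explicit mask or the mouse `mt-` symbol prefix
(case-insensitive). Depth-normalize each kept cell to 10,000 counts and
log1p. Keep the top 3,000 highly variable genes (dispersion statistic:
variance of the log-normalized values; ties to the lower gene index).
PCA to 20 components; build a symmetrized exact 15-nearest-neighbor
graph on the scores.

Two deliberate design choices:

- **Normalization.** Regression-based variance stabilization (as in
  SCTransform-style normalizers) is not re-implemented; depth scaling +
  log1p is the default and `preprocess_pipeline` accepts any
  `normalizer` callable. The selection logic downstream is
  normalization-agnostic by contract.
- **PCA scaling.** Genes are centered but *not* scaled to unit variance
  by default. With HVG selection already applied, per-gene unit scaling
  equalizes strongly and weakly variable genes and lets the latter
  dominate the embedding; empirically it degrades type recovery at
  k = 8 on the package's own simulations (ARI ≈ 0.93 scaled vs ≈ 0.99
  centered-only), and it destroys the exact-isometry property of PCA on
  low-rank data that the test suite checks. `scale=True` is available.

PCA component signs are fixed (largest-magnitude loading positive) so
embeddings are bit-reproducible across linear-algebra backends.

## Annotation

The marker score formalizes visual feature-plot annotation: per gene,
z-score the cluster-mean expression across clusters; score(cluster,
type) = mean z over the type's markers present in the data; assign each
cluster the argmax type, ties to the earlier table entry. Missing
markers are excluded and reported as per-type coverage. This score is a
pragmatic formalization, not a canonical statistic, and the function is
swappable. Gene symbols match case-sensitively with a case-insensitive
fallback that warns (mouse symbol casing is error-prone across
datasets).

The packaged mouse-skin panel (24 entries: fibroblast, keratinocyte,
T-cell, myeloid, endothelial, mural, melanocyte subsets) is transcribed
verbatim from its source panel, including its inconsistent hair-follicle
subset naming (HFH-I vs HFK-I); the two HFK-II rows were merged because
cell-type names must be unique. User tables override it.

## Dendrogram and composition

Cluster centroids are means over the HVG log-normalized matrix
(configurable to PCA space). Ward linkage runs via the Lance–Williams
recurrence on squared Euclidean distances, heights reported on the
Euclidean scale (singletons merge at their plain distance), minimum-
distance ties broken toward the lowest (i, j) pair. The test oracle
re-derives every merge from scratch by recomputing the within-cluster
sum-of-squares increase of all candidate merges. Newick export makes
the tree ultrametric (branch = parent height − child height, leaves at
height 0), with standard single-quote escaping. No attempt is made to
reproduce any particular published dendrogram's height axis — that
depends on the expression space used — only internal consistency is
tested. Average linkage is a config stub, not implemented.

Composition tables report exact counts and within-condition percentages
(summing to 100 within 1e-9), conditions ordered by first appearance,
types by descending pooled abundance, absent types reported as zero.

## Synthetic data

`simulate_counts` draws gamma–Poisson (negative-binomial) counts,
var = μ + φμ², with shared dispersion φ = 0.5 and base mean 0.5 per
gene — realistic magnitudes for shallow droplet data, giving ~500 total
UMIs per 1,000-gene cell, inside the default QC window. Each of k types
gets 5 exclusive marker genes elevated 2×/5×/20× (low/medium/high
separation); cell depth is log-normal (σ = 0.3); 10 `mt-` genes are
tuned to an expected 5% mitochondrial fraction; conditions split cells
evenly and draw types from per-condition proportion vectors. One
`numpy.random.default_rng` (PCG64) stream per run makes output
bit-reproducible per (config, seed). A `two_condition_preset` ships a
control/wounded demonstration in which one type expands 0.5% → 11% and
another collapses 17% → 1.5%.

What passing recovery tests show — and don't: the generator produces
discrete, well-separated types without gene–gene correlation, batch
structure, doublets or continuous trajectories, so recovery there
demonstrates the selection machinery is correct, not that the selected
resolution is biologically optimal on any real tissue.

On these simulations the silhouette values themselves are modest (peak
≈ 0.15 for well-recovered partitions vs ≈ 0.08 for a single-type null):
NB sampling noise fills the non-signal PCA dimensions, inflating a(i)
relative to an idealized Gaussian-blob picture. The selection argmax is
unaffected, which is the property the method relies on.

## Problem sizes used in the shipped checks

Recovery runs use 1,500 cells × 1,000 genes at k ∈ {3, 5, 8} (five
seeds each), the null control 800 cells, and the subsample-fidelity
check 5,000 cells — sizes at which every property of interest is
already stable and the whole suite stays quick to run.

## Known limitations

- Dense in-memory matrices throughout; intended for 10³–10⁵ cells, not
  atlas-scale sparse data.
- Exact kNN (no approximate search); O(n²) silhouette unless the
  subsample option is used.
- No doublet detection, ambient-RNA correction, or batch integration.
- Alternative selection criteria (Calinski–Harabasz, Davies–Bouldin,
  stability resampling) are future work.
- UMAP computation is deliberately out of the tested core; feature-plot
  export takes any user-supplied 2-D embedding.
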