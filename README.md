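# scresolve

Silhouette-guided selection of the optimal clustering resolution for
single-cell RNA-seq, with the surrounding analysis stages needed to use
it end to end: QC filtering, normalization, HVG/PCA preprocessing,
marker-driven cluster annotation, Ward dendrograms of cell-type
centroids, condition-wise composition comparison, and a synthetic-data
generator with ground truth.

## Who it is for

Anyone clustering cells with graph community detection (Leiden/Louvain
on a kNN cell graph) who wants the resolution parameter chosen by an
explicit, reproducible criterion instead of visual inspection — e.g.
when mapping cell-type composition shifts between experimental
conditions such as control vs wounded skin.

## The method

For every resolution r in a grid (default 0.10–1.50, step 0.02) the
cell kNN graph is clustered; each partition is scored by the mean
silhouette on the PCA embedding,

    S(i) = (b(i) − a(i)) / max(a(i), b(i)),      S = (1/n) Σᵢ S(i),

where a(i) is the mean distance from cell i to its own cluster's other
members and b(i) the smallest mean distance to another cluster.
Singleton-cluster cells contribute S(i) = 0; single-cluster partitions
are unscored and excluded. The selected resolution is the argmax of S,
ties broken toward the lowest resolution. Details, conventions, and the
design rationale are in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a two-condition dataset (5 cell types; one type expands from
0.5% of control cells to 11% of wounded cells, another collapses from
17% to 1.5%), then sweep:

```bash
scresolve simulate --n-cells 1000 --n-genes 800 --seed 0 --two-conditions --out data
scresolve sweep --mtx-dir data --seed 0 --out run
```

which logs

```
QC kept 996/1000 cells; 800 HVGs, 20 PCs
optimal resolution 0.6 with k=5 clusters (mean silhouette 0.1434)
```

The sweep table (`run/sweep.tsv`) shows the mean silhouette rising as
the grid splits the data toward the true 5 types and peaking at the
selected resolution:

```
resolution  k  mean_silhouette
0.1         3  0.121184333088849
0.22        4  0.1307612615026488
0.6         5  0.14339553317790626   <- selected
```

The selected partition (`run/partition.tsv`) recovers the generator's 5
types. Comparing composition between conditions (the generator's
`truth.tsv` records each cell's condition; any two-column
cell_id/condition TSV works):

```bash
cut -f1,3 data/truth.tsv > cond.tsv
scresolve compose --partition run/partition.tsv --conditions cond.tsv --out comp
```

```
condition  cell_type  count  percent
wounded    3          71     13.25
wounded    4          6      1.12
control    3          3      0.65
control    4          66     14.35
```

(selected rows; percentages rounded here — the file carries full
precision)

i.e. cluster 3 expands from 0.65% of control cells to 13.25% of wounded
cells and cluster 4 collapses from 14.35% to 1.12% — the composition
shifts the generator planted, read back from the selected clustering.
`scresolve annotate` scores clusters against a marker table (a packaged
mouse-skin panel by default), `scresolve dendro` writes a Ward
dendrogram of cluster centroids as Newick, and `scresolve pipeline`
chains all stages. Every command writes a `manifest.json` (resolved
config, seeds, version, input checksums) and reruns byte-identically.

The same functionality is available as a library:

```python
from scresolve import SimConfig, SweepConfig, simulate_counts, preprocess_pipeline, run_sweep

sim = simulate_counts(SimConfig(n_cells=1500, n_genes=1000, k_types=5, seed=0))
counts, norm, embedding, graph, report = preprocess_pipeline(sim.counts)
result = run_sweep(embedding, graph, SweepConfig(seed=0))
print(result.optimal_resolution, result.optimal_partition.k)
```

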