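"""Resolution sweep: cluster at each grid resolution, score by mean
silhouette, select the optimum.

Modularity-style community detection (Leiden by default, Louvain
selectable) is run on the cell kNN graph at every resolution in an
inclusive grid.  Each multi-cluster partition is scored by the mean
silhouette on the PCA embedding (optionally on a cluster-stratified
subsample for large data sets); the resolution maximizing the mean
silhouette is selected, ties going to the LOWEST resolution (fewer,
coarser clusters preferred at equal quality).  Single-cluster
partitions are unscored — the silhouette is undefined there — and can
therefore never win or lose on an arbitrary constant.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from typing import Literal, Optional

import igraph as ig
import leidenalg
import numpy as np

from .core import (
    Embedding,
    Partition,
    SweepEntry,
    SweepResult,
    silhouette_score,
)
from .preprocess import NeighborGraph

__all__ = [
    "SweepConfig",
    "NoScoreablePartitionError",
    "cluster_at_resolution",
    "run_sweep",
    "stratified_subsample",
    "sweep_result_to_json",
    "sweep_result_to_tsv",
]


class NoScoreablePartitionError(ValueError):
    """Every grid point produced fewer than min_k clusters."""


@dataclass
class SweepConfig:
    """Grid and scoring options for a resolution sweep.

    The grid is built by integer index (r_i = res_min + i * res_step,
    inclusive of res_max up to floating-point slack), so removing a
    grid point never shifts another point's clustering seed.  The
    default step of 0.02 resolves two-decimal optima.
    """

    res_min: float = 0.10
    res_max: float = 1.50
    res_step: float = 0.02
    algorithm: Literal["leiden", "louvain"] = "leiden"
    seed: int = 0
    silhouette_subsample: Optional[int] = None
    min_k: int = 2

    def __post_init__(self) -> None:
        if not (self.res_min > 0 and self.res_max > 0 and self.res_step > 0):
            raise ValueError("resolutions and step must be positive")
        if self.res_min > self.res_max:
            raise ValueError("res_min must be <= res_max")
        if self.algorithm not in ("leiden", "louvain"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.silhouette_subsample is not None and self.silhouette_subsample < 50:
            raise ValueError("silhouette_subsample must be >= 50 when set")

    def grid(self) -> list[float]:
        n = int(np.floor((self.res_max - self.res_min) / self.res_step + 1e-9)) + 1
        return [round(self.res_min + i * self.res_step, 10) for i in range(n)]


def _to_igraph(graph: NeighborGraph) -> ig.Graph:
    g = ig.Graph(n=graph.n_cells, edges=[tuple(e) for e in graph.edges])
    g.es["weight"] = list(graph.weights)
    return g


def _relabel_by_size(membership: list[int]) -> np.ndarray:
    """Relabel clusters contiguous 0..k-1 by descending size (ties by
    ascending original label)."""
    arr = np.asarray(membership)
    labs, counts = np.unique(arr, return_counts=True)
    order = labs[np.argsort(-counts, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(x)] for x in arr])


def cluster_at_resolution(
    graph: NeighborGraph,
    resolution: float,
    algorithm: Literal["leiden", "louvain"] = "leiden",
    seed: int = 0,
) -> Partition:
    """Community detection at one resolution.

    Labels are relabeled contiguous 0..k-1 by descending cluster size;
    the result is deterministic for fixed (graph, resolution, seed).
    """
    if graph.n_cells == 0:
        raise ValueError("empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    g = _to_igraph(graph)
    if algorithm == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        membership = part.membership
    elif algorithm == "louvain":
        rng = random.Random(seed)
        ig.set_random_number_generator(rng)
        try:
            part = g.community_multilevel(weights="weight", resolution=resolution)
        finally:
            ig.set_random_number_generator(random)
        membership = part.membership
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    labels = _relabel_by_size(membership)
    return Partition(
        labels=labels,
        resolution=resolution,
        seed=seed,
        algorithm=algorithm,
        cell_ids=graph.cell_ids,
    )


def stratified_subsample(partition: Partition, target_n: int, seed: int = 0) -> np.ndarray:
    """Cluster-stratified cell indices of size ``target_n``.

    Every cluster contributes at least one cell; quotas are proportional
    to cluster size with largest-remainder rounding (remainder ties
    resolved by ascending cluster id).  Deterministic per seed.
    """
    labels = partition.labels
    n = labels.size
    k = partition.k
    if target_n < k:
        raise ValueError(f"target_n={target_n} is below the number of clusters ({k})")
    if target_n >= n:
        return np.arange(n)
    sizes = np.bincount(labels, minlength=k)
    # proportional quotas with a floor of 1 per cluster
    raw = sizes * (target_n / n)
    quotas = np.maximum(np.floor(raw).astype(int), 1)
    quotas = np.minimum(quotas, sizes)
    remainder = raw - np.floor(raw)
    # distribute leftover seats by descending remainder, ties by cluster id
    while quotas.sum() < target_n:
        order = np.lexsort((np.arange(k), -remainder))
        placed = False
        for c in order:
            if quotas[c] < sizes[c]:
                quotas[c] += 1
                remainder[c] = -1.0
                placed = True
                break
        if not placed:
            break
    while quotas.sum() > target_n:
        # floor-of-1 rule can overshoot with many tiny clusters; trim the
        # largest quotas first (ties by descending cluster id)
        order = np.lexsort((-np.arange(k), -quotas))
        for c in order:
            if quotas[c] > 1:
                quotas[c] -= 1
                break
        else:
            break
    rng = np.random.default_rng(seed)
    chosen = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if quotas[c] >= members.size:
            chosen.append(members)
        else:
            chosen.append(rng.choice(members, size=quotas[c], replace=False))
    return np.sort(np.concatenate(chosen))


def run_sweep(
    embedding: Embedding, graph: NeighborGraph, config: SweepConfig = SweepConfig()
) -> SweepResult:
    """Cluster and silhouette-score every grid resolution, pick the best.

    Partitions with fewer than ``config.min_k`` clusters are recorded
    with ``mean_silhouette = None`` and excluded from the optimization.
    Raises if no grid point yields a scoreable partition.
    """
    if embedding.cell_ids != graph.cell_ids:
        raise ValueError("embedding and graph are not aligned on cells")
    entries: list[SweepEntry] = []
    for i, res in enumerate(config.grid()):
        part = cluster_at_resolution(
            graph, res, algorithm=config.algorithm, seed=config.seed + i
        )
        if part.k < max(config.min_k, 2):
            entries.append(SweepEntry(res, part.k, None, part))
            continue
        if config.silhouette_subsample is not None and config.silhouette_subsample < part.n_cells:
            idx = stratified_subsample(part, config.silhouette_subsample, seed=config.seed)
            sub_emb = Embedding(embedding.coords[idx], [embedding.cell_ids[j] for j in idx])
            sub_part = Partition(
                labels=_relabel_by_size(part.labels[idx].tolist()),
                resolution=res,
                seed=part.seed,
                algorithm=part.algorithm,
                cell_ids=sub_emb.cell_ids,
            )
            sil = silhouette_score(sub_emb, sub_part)
        else:
            sil = silhouette_score(embedding, part)
        entries.append(SweepEntry(res, part.k, sil.mean, part))

    best: Optional[SweepEntry] = None
    for e in entries:  # ascending resolution; strict > keeps the lowest at ties
        if e.mean_silhouette is None:
            continue
        if best is None or e.mean_silhouette > best.mean_silhouette:
            best = e
    if best is None:
        raise NoScoreablePartitionError("no multi-cluster partition in grid")
    return SweepResult(
        entries=entries,
        optimal_resolution=best.resolution,
        optimal_partition=best.partition,
        config=asdict(config),
    )


def sweep_result_to_json(result: SweepResult) -> str:
    payload = {
        "config": result.config,
        "optimal_resolution": result.optimal_resolution,
        "optimal_k": result.optimal_partition.k,
        "grid": [
            {
                "resolution": e.resolution,
                "k": e.k,
                "mean_silhouette": e.mean_silhouette,
            }
            for e in result.entries
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def sweep_result_to_tsv(result: SweepResult) -> str:
    lines = ["resolution\tk\tmean_silhouette"]
    for e in result.entries:
        ms = "NA" if e.mean_silhouette is None else repr(e.mean_silhouette)
        lines.append(f"{e.resolution}\t{e.k}\t{ms}")
    return "\n".join(lines) + "\n"
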