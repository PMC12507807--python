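"""Domain types and silhouette mathematics.

The silhouette coefficient of a cell *i* in a partition is

    S(i) = (b(i) - a(i)) / max(a(i), b(i))

where ``a(i)`` is the mean distance from *i* to the other members of its
own cluster and ``b(i)`` is the smallest mean distance from *i* to the
members of any other cluster.  The partition-level score is the
arithmetic mean of S(i) over all cells; cells in singleton clusters
contribute S(i) = 0 but still count in the denominator.  Distances are
Euclidean on the supplied embedding (typically PCA space — the same
space the cell neighbor graph is built on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "CountMatrix",
    "Embedding",
    "Partition",
    "SilhouetteResult",
    "SweepEntry",
    "SweepResult",
    "silhouette_score",
    "brute_force_silhouette",
    "AlignmentError",
    "UndefinedSilhouetteError",
]


class AlignmentError(ValueError):
    """Cell identifiers of two objects do not line up."""


class UndefinedSilhouetteError(ValueError):
    """Silhouette requested for a partition with fewer than 2 clusters."""


@dataclass
class CountMatrix:
    """Raw gene x cell UMI counts with identifiers and a mitochondrial flag.

    Parameters
    ----------
    values
        Non-negative integer matrix, genes as rows, cells as columns.
    gene_ids, cell_ids
        Unique, ordered identifiers matching the rows / columns.
    mito_mask
        Boolean per gene; True marks a mitochondrial gene.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    mito_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-D (genes x cells)")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.floor(self.values)):
                raise ValueError("counts must be integral")
            self.values = self.values.astype(np.int64)
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match row count")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match column count")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell_ids")
        if self.mito_mask.shape != (n_genes,):
            raise ValueError("mito_mask length does not match gene count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """Cells x d real-valued coordinates (usually PCA scores)."""

    coords: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = list(self.cell_ids)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D (cells x d)")
        if self.coords.shape[1] < 1:
            raise ValueError("embedding dimension must be >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite values")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell_ids length does not match row count")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class Partition:
    """A clustering of cells at one resolution.

    ``labels`` are contiguous small integers 0..k-1 (0 = largest cluster
    when produced by the sweep).  ``resolution``, ``seed`` and
    ``algorithm`` record provenance.
    """

    labels: np.ndarray
    resolution: float
    seed: int
    algorithm: Literal["leiden", "louvain"]
    cell_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a vector")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() != len(set(self.labels.tolist())) - 1
        ):
            raise ValueError("labels must be contiguous integers 0..k-1")
        if self.cell_ids is not None:
            self.cell_ids = list(self.cell_ids)
            if len(self.cell_ids) != self.labels.size:
                raise ValueError("cell_ids length does not match labels")

    @property
    def k(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def n_cells(self) -> int:
        return self.labels.size


@dataclass
class SilhouetteResult:
    """Per-cell silhouettes S(i) and their mean."""

    per_cell: np.ndarray
    mean: float
    n_scored: int

    def __post_init__(self) -> None:
        self.per_cell = np.asarray(self.per_cell, dtype=float)


@dataclass
class SweepEntry:
    resolution: float
    k: int
    mean_silhouette: Optional[float]  # None = unscored (k < min_k)
    partition: Partition


@dataclass
class SweepResult:
    """Outcome of a resolution sweep: one entry per grid point plus the optimum."""

    entries: list[SweepEntry]
    optimal_resolution: float
    optimal_partition: Partition
    config: dict = field(default_factory=dict)


def _check_alignment(embedding: Embedding, partition: Partition) -> None:
    if partition.n_cells != embedding.n_cells:
        raise AlignmentError(
            f"partition has {partition.n_cells} cells but embedding has {embedding.n_cells}"
        )
    if partition.cell_ids is not None and partition.cell_ids != embedding.cell_ids:
        raise AlignmentError("cell_ids of embedding and partition differ")


def silhouette_score(
    embedding: Embedding,
    partition: Partition,
    metric: Literal["euclidean"] = "euclidean",
) -> SilhouetteResult:
    """Silhouette S(i) for every cell and the partition mean.

    Cells in singleton clusters receive S(i) = 0 (and still count in the
    mean).  The degenerate case max(a, b) = 0 — two clusters of mutually
    coincident points — also yields S(i) = 0.

    Raises
    ------
    UndefinedSilhouetteError
        If the partition has fewer than 2 clusters.
    AlignmentError
        If embedding and partition are not aligned on cells.
    """
    if metric != "euclidean":
        raise ValueError(f"unsupported metric: {metric!r}")
    _check_alignment(embedding, partition)
    labels = partition.labels
    k = partition.k
    if k < 2:
        raise UndefinedSilhouetteError("silhouette undefined for fewer than 2 clusters")
    n = embedding.n_cells
    if n < 3:
        raise ValueError("silhouette needs at least 3 cells")

    X = embedding.coords
    sizes = np.bincount(labels, minlength=k).astype(float)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0

    # Row-chunked distance accumulation keeps memory at O(chunk * n).
    # cdist computes exact coordinate-difference distances (no Gram-matrix
    # shortcut, whose cancellation error would spoil near-duplicate points).
    from scipy.spatial.distance import cdist

    sums = np.empty((n, k))
    chunk = max(1, int(2**25 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(X[start:stop], X)
        sums[start:stop] = d @ onehot

    own = sizes[labels]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(own > 1, sums[np.arange(n), labels] / np.maximum(own - 1, 1), 0.0)
        mean_to = sums / sizes[None, :]
    mean_to[np.arange(n), labels] = np.inf
    b = mean_to.min(axis=1)

    denom = np.maximum(a, b)
    s = np.zeros(n)
    ok = denom > 0
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    s[own == 1] = 0.0  # singleton convention
    return SilhouetteResult(per_cell=s, mean=float(s.mean()), n_scored=n)


def brute_force_silhouette(embedding: Embedding, partition: Partition) -> SilhouetteResult:
    """Reference silhouette by explicit double loop over all cell pairs.

    Independent of :func:`silhouette_score` — no shared code paths — and
    O(n^2) in pure Python; intended as a test oracle on small inputs.
    """
    _check_alignment(embedding, partition)
    labels = [int(x) for x in partition.labels]
    k = len(set(labels))
    if k < 2:
        raise UndefinedSilhouetteError("silhouette undefined for fewer than 2 clusters")
    n = embedding.n_cells
    if n < 3:
        raise ValueError("silhouette needs at least 3 cells")
    pts: list[Sequence[float]] = [tuple(row) for row in embedding.coords]
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(i)

    per_cell = []
    for i in range(n):
        own = clusters[labels[i]]
        if len(own) == 1:
            per_cell.append(0.0)
            continue
        a = sum(math.dist(pts[i], pts[j]) for j in own if j != i) / (len(own) - 1)
        b = math.inf
        for lab, members in clusters.items():
            if lab == labels[i]:
                continue
            m = sum(math.dist(pts[i], pts[j]) for j in members) / len(members)
            b = min(b, m)
        denom = max(a, b)
        per_cell.append(0.0 if denom == 0 else (b - a) / denom)
    arr = np.array(per_cell)
    return SilhouetteResult(per_cell=arr, mean=float(arr.mean()), n_scored=n)
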