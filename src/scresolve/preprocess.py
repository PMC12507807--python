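"""Quality control and dimensionality reduction ahead of the resolution sweep.

Defaults follow a conventional droplet scRNA-seq pipeline for mouse
skin: cells with fewer than 200 or more than 2500 total UMIs, or more
than 10% mitochondrial counts, are discarded; the top 3000 highly
variable genes feed a 20-component PCA, on which a k-nearest-neighbor
cell graph is built for community detection.

Normalization is per-cell depth scaling to a fixed target sum followed
by log1p.  Regression-based normalizers (e.g. variance-stabilizing NB
regression) can be plugged in via the ``normalizer`` hook of
:func:`preprocess_pipeline`; the selection logic downstream is agnostic
to the choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core import CountMatrix, Embedding

__all__ = [
    "QCParams",
    "PreprocessReport",
    "NeighborGraph",
    "qc_filter",
    "normalize",
    "select_hvg",
    "pca_embed",
    "build_neighbor_graph",
    "preprocess_pipeline",
]

MITO_PREFIX = "mt-"  # mouse convention; matched case-insensitively


@dataclass
class QCParams:
    """Cell-level QC bounds.

    A cell is kept iff ``min_umi <= total UMI <= max_umi`` and its
    mitochondrial count fraction is ``<= max_mito_frac`` (the stated
    bounds are strict: "fewer than 200", "more than 2500", "exceeding
    10%", so boundary values pass).
    """

    min_umi: int = 200
    max_umi: int = 2500
    max_mito_frac: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.min_umi <= self.max_umi):
            raise ValueError("require 0 <= min_umi <= max_umi")
        if not (0.0 <= self.max_mito_frac <= 1.0):
            raise ValueError("max_mito_frac must be in [0, 1]")


@dataclass
class PreprocessReport:
    n_cells_in: int
    n_cells_kept: int
    n_genes_hvg: int = 3000
    n_pcs: int = 20
    per_cell: pd.DataFrame = field(default_factory=pd.DataFrame)
    # per_cell columns: cell_id, umi_total, mito_frac, kept, reason

    def to_json_summary(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_kept": self.n_cells_kept,
            "n_genes_hvg": self.n_genes_hvg,
            "n_pcs": self.n_pcs,
        }


@dataclass
class NeighborGraph:
    """Symmetric weighted kNN graph over the kept cells.

    ``edges`` is an (m, 2) int array of unique undirected pairs (i < j)
    with parallel ``weights``; ``cell_ids`` orders the nodes.
    """

    edges: np.ndarray
    weights: np.ndarray
    n_cells: int
    k_neighbors: int
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops not allowed")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")


def ensure_mito_mask(gene_ids: list[str], mito_mask: Optional[np.ndarray]) -> np.ndarray:
    """Return the given mask, or derive one from the mt- symbol prefix."""
    if mito_mask is not None:
        return np.asarray(mito_mask, dtype=bool)
    mask = np.array([g.lower().startswith(MITO_PREFIX) for g in gene_ids])
    return mask


def qc_filter(counts: CountMatrix, params: QCParams = QCParams()) -> tuple[CountMatrix, PreprocessReport]:
    """Drop low/high-depth and high-mitochondrial cells.

    Each discarded cell records exactly one (first-failing) reason, in
    the order ``low_umi``, ``high_umi``, ``high_mito``.  Keeping zero
    cells warns rather than raising.
    """
    totals = counts.values.sum(axis=0)
    if not counts.mito_mask.any() and not any(
        g.lower().startswith(MITO_PREFIX) for g in counts.gene_ids
    ):
        # No annotation and no recognizable symbols: mito fraction is 0
        # for every cell, which silently disables the mito bound.
        warnings.warn(
            "no mitochondrial genes flagged or recognizable by prefix 'mt-'; "
            "mitochondrial QC bound has no effect",
            stacklevel=2,
        )
    mito_counts = counts.values[counts.mito_mask].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    reasons = np.full(counts.n_cells, "", dtype=object)
    reasons[totals < params.min_umi] = "low_umi"
    high = (reasons == "") & (totals > params.max_umi)
    reasons[high] = "high_umi"
    mito_bad = (reasons == "") & (mito_frac > params.max_mito_frac)
    reasons[mito_bad] = "high_mito"
    kept = reasons == ""

    per_cell = pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "umi_total": totals.astype(int),
            "mito_frac": mito_frac,
            "kept": kept,
            "reason": reasons,
        }
    )
    report = PreprocessReport(
        n_cells_in=counts.n_cells, n_cells_kept=int(kept.sum()), per_cell=per_cell
    )
    if report.n_cells_kept == 0:
        warnings.warn("QC filter retained zero cells", stacklevel=2)
    filtered = CountMatrix(
        values=counts.values[:, kept],
        gene_ids=counts.gene_ids,
        cell_ids=[c for c, k in zip(counts.cell_ids, kept) if k],
        mito_mask=counts.mito_mask,
    )
    return filtered, report


def normalize(counts: CountMatrix, target_sum: float = 10_000.0) -> np.ndarray:
    """Depth-normalize each cell to ``target_sum`` total, then log1p.

    Returns a dense float matrix (genes x cells).  Proportional count
    vectors map to identical columns (depth invariance).
    """
    totals = counts.values.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("cannot normalize cells with zero total count")
    scaled = counts.values / totals[None, :] * target_sum
    return np.log1p(scaled)


def select_hvg(norm: np.ndarray, n_top: int = 3000) -> np.ndarray:
    """Indices of the top highly variable genes.

    Dispersion statistic: per-gene variance of the log-normalized
    values.  Genes with zero variance are never selected; ties are
    broken toward the lower gene index.  Returns at most
    min(n_top, #genes with positive variance) indices.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    var = norm.var(axis=1)
    positive = np.flatnonzero(var > 0)
    if positive.size == 0:
        raise ValueError("no variable genes")
    # stable sort on -var keeps ascending index order within ties
    order = positive[np.argsort(-var[positive], kind="stable")]
    return np.sort(order[: min(n_top, positive.size)])


def pca_embed(
    norm_hvg: np.ndarray,
    cell_ids: list[str],
    n_pcs: int = 20,
    seed: int = 0,
    scale: bool = False,
) -> Embedding:
    """PCA scores of the cells on the centered HVG matrix.

    ``norm_hvg`` is genes x cells.  Genes are centered but, by default,
    not scaled to unit variance: with HVG selection already applied,
    unit scaling flattens the very expression-magnitude differences
    that separate cell types and lets the many weakly variable genes
    dominate the embedding (it also breaks the exact isometry of PCA on
    low-rank data).  Set ``scale=True`` for the variance-scaled
    variant.  Component signs are fixed so that each component's
    largest-magnitude gene loading is positive, making embeddings
    reproducible across linear-algebra backends.
    """
    n_genes, n_cells = norm_hvg.shape
    max_pcs = min(n_cells - 1, n_genes)
    if n_pcs > max_pcs:
        raise ValueError(f"n_pcs={n_pcs} too large; maximum is {max_pcs}")
    X = norm_hvg.T.astype(float)  # cells x genes
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    # deterministic sign convention
    for j in range(n_pcs):
        load = pca.components_[j]
        i_max = int(np.argmax(np.abs(load)))
        if load[i_max] < 0:
            scores[:, j] = -scores[:, j]
    return Embedding(coords=scores, cell_ids=list(cell_ids))


def build_neighbor_graph(
    embedding: Embedding, k_neighbors: int = 15, seed: int = 0
) -> NeighborGraph:
    """Symmetrized k-nearest-neighbor graph in the embedding.

    Each cell is linked to its k nearest Euclidean neighbors; the union
    of directed links becomes an undirected edge set with weight 1.
    Deterministic for a fixed embedding (``seed`` is accepted for
    interface symmetry; the exact search has no randomness).
    """
    n = embedding.n_cells
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1, algorithm="auto")
    nn.fit(embedding.coords)
    _, idx = nn.kneighbors(embedding.coords)
    rows = np.repeat(np.arange(n), k_neighbors)
    cols = idx[:, 1:].ravel()  # drop self (first neighbor)
    # drop residual self matches (possible with duplicated points)
    keep = rows != cols
    rows, cols = rows[keep], cols[keep]
    lo, hi = np.minimum(rows, cols), np.maximum(rows, cols)
    pairs = np.unique(np.stack([lo, hi], axis=1), axis=0)
    return NeighborGraph(
        edges=pairs,
        weights=np.ones(len(pairs)),
        n_cells=n,
        k_neighbors=k_neighbors,
        cell_ids=embedding.cell_ids,
    )


def preprocess_pipeline(
    counts: CountMatrix,
    qc_params: QCParams = QCParams(),
    n_hvg: int = 3000,
    n_pcs: int = 20,
    k_neighbors: int = 15,
    seed: int = 0,
    normalizer: Callable[[CountMatrix], np.ndarray] = normalize,
) -> tuple[CountMatrix, np.ndarray, Embedding, NeighborGraph, PreprocessReport]:
    """QC -> normalize -> HVG -> PCA -> kNN graph, with one report.

    Returns (filtered counts, normalized matrix over all genes, PCA
    embedding, neighbor graph, report).
    """
    filtered, report = qc_filter(counts, qc_params)
    if filtered.n_cells == 0:
        raise ValueError("QC retained zero cells; nothing to preprocess")
    norm = normalizer(filtered)
    hvg_idx = select_hvg(norm, n_top=n_hvg)
    n_pcs_eff = min(n_pcs, min(filtered.n_cells - 1, hvg_idx.size))
    embedding = pca_embed(norm[hvg_idx], filtered.cell_ids, n_pcs=n_pcs_eff, seed=seed)
    graph = build_neighbor_graph(embedding, k_neighbors=min(k_neighbors, filtered.n_cells - 1), seed=seed)
    report.n_genes_hvg = int(hvg_idx.size)
    report.n_pcs = n_pcs_eff
    return filtered, norm, embedding, graph, report
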