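"""Marker-driven cluster annotation and feature-plot export.

Annotation here formalizes what is usually done by eye with feature
plots: for every gene, the per-cluster mean expression is z-scored
across clusters; a cluster's score for a cell type is the mean z-score
over that type's marker genes present in the data.  Each cluster is
assigned the argmax cell type, ties going to the earlier marker-table
entry.  The score is a pragmatic formalization of visual marker
inspection, not a canonical statistic, and is kept swappable.

A default marker panel for mouse skin (fibroblast, keratinocyte, T
cell, myeloid, endothelial, mural and melanocyte subsets) ships as a
packaged TSV resource; user tables override it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources as _resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Embedding, Partition

__all__ = [
    "MarkerTable",
    "AnnotationResult",
    "load_marker_table",
    "default_marker_table",
    "score_clusters",
    "feature_plot_data",
]


@dataclass
class MarkerTable:
    """Ordered mapping cell-type name -> marker gene symbols."""

    entries: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.entries.items():
            if not name:
                raise ValueError("empty cell-type name")
            if not genes or any(not g for g in genes):
                raise ValueError(f"cell type {name!r} has an empty marker list/symbol")

    @property
    def cell_types(self) -> list[str]:
        return list(self.entries)


@dataclass
class AnnotationResult:
    score_matrix: pd.DataFrame  # clusters x cell types
    assignment: dict[int, str]
    coverage: pd.DataFrame  # clusters x cell types, fraction of markers found
    missing_genes: dict[str, list[str]]  # cell type -> markers absent from data


def load_marker_table(path: str | Path) -> MarkerTable:
    """Read a marker TSV with columns ``cell_type`` and ``markers``
    (comma-separated gene symbols).  Lines starting with '#' are skipped."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"cell_type", "markers"} <= set(df.columns):
        raise ValueError("marker table needs columns: cell_type, markers")
    entries: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        name = str(row["cell_type"]).strip()
        genes = [g.strip() for g in str(row["markers"]).split(",") if g.strip()]
        if name in entries:
            raise ValueError(f"duplicate cell type {name!r} in marker table")
        entries[name] = genes
    return MarkerTable(entries)


def default_marker_table() -> MarkerTable:
    """The packaged mouse-skin marker panel."""
    ref = _resources.files("scresolve") / "resources" / "markers_mouse_skin.tsv"
    with _resources.as_file(ref) as path:
        return load_marker_table(path)


def _match_genes(
    wanted: list[str], gene_ids: list[str]
) -> tuple[list[int], list[str]]:
    """Indices of wanted genes; case-sensitive first, then a
    case-insensitive fallback with a warning."""
    index = {g: i for i, g in enumerate(gene_ids)}
    lower = {}
    for i, g in enumerate(gene_ids):
        lower.setdefault(g.lower(), i)
    found, missing = [], []
    for g in wanted:
        if g in index:
            found.append(index[g])
        elif g.lower() in lower:
            warnings.warn(
                f"marker {g!r} matched case-insensitively to "
                f"{gene_ids[lower[g.lower()]]!r}",
                stacklevel=3,
            )
            found.append(lower[g.lower()])
        else:
            missing.append(g)
    return found, missing


def score_clusters(
    norm: np.ndarray,
    gene_ids: list[str],
    partition: Partition,
    markers: MarkerTable,
) -> AnnotationResult:
    """Score every cluster against every marker set and assign types.

    ``norm`` is the genes x cells normalized matrix aligned with
    ``gene_ids`` (rows) and the partition (columns).
    """
    if norm.shape[1] != partition.n_cells:
        raise ValueError("normalized matrix and partition are not aligned on cells")
    if norm.shape[0] != len(gene_ids):
        raise ValueError("normalized matrix and gene_ids are not aligned on genes")
    k = partition.k
    labels = partition.labels
    # cluster-mean expression, genes x clusters
    means = np.stack(
        [norm[:, labels == c].mean(axis=1) for c in range(k)], axis=1
    )
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (means - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    types = markers.cell_types
    scores = np.full((k, len(types)), np.nan)
    coverage = np.zeros((k, len(types)))
    missing_genes: dict[str, list[str]] = {}
    any_found = False
    for j, t in enumerate(types):
        found, missing = _match_genes(markers.entries[t], gene_ids)
        missing_genes[t] = missing
        frac = len(found) / len(markers.entries[t])
        coverage[:, j] = frac
        if found:
            any_found = True
            scores[:, j] = z[found].mean(axis=0)
    if not any_found:
        raise ValueError("marker table disjoint from data")

    score_df = pd.DataFrame(scores, index=range(k), columns=types)
    cov_df = pd.DataFrame(coverage, index=range(k), columns=types)
    assignment: dict[int, str] = {}
    for c in range(k):
        row = scores[c]
        valid = ~np.isnan(row)
        best = np.flatnonzero(valid & (row == np.nanmax(row)))[0]  # table order wins ties
        assignment[c] = types[int(best)]
    return AnnotationResult(
        score_matrix=score_df,
        assignment=assignment,
        coverage=cov_df,
        missing_genes=missing_genes,
    )


def feature_plot_data(
    norm: np.ndarray,
    gene_ids: list[str],
    embedding2d: Embedding,
    genes: list[str],
) -> pd.DataFrame:
    """Long-form table (cell_id, x, y, gene, value) for feature plots.

    ``embedding2d`` must be 2-D (e.g. a UMAP layout).  Requested genes
    absent from the matrix produce zero rows and a warning.
    """
    if embedding2d.d != 2:
        raise ValueError(f"feature plots need a 2-D embedding, got d={embedding2d.d}")
    if norm.shape[1] != embedding2d.n_cells:
        raise ValueError("normalized matrix and embedding are not aligned on cells")
    index = {g: i for i, g in enumerate(gene_ids)}
    present = []
    for g in genes:
        if g in index:
            present.append(g)
        else:
            warnings.warn(f"requested gene {g!r} absent from the matrix", stacklevel=2)
    if not present:
        return pd.DataFrame(columns=["cell_id", "x", "y", "gene", "value"])
    n = embedding2d.n_cells
    m = len(present)
    vals = norm[[index[g] for g in present]].T  # cells x genes
    return pd.DataFrame(
        {
            "cell_id": np.repeat(embedding2d.cell_ids, m),
            "x": np.repeat(embedding2d.coords[:, 0], m),
            "y": np.repeat(embedding2d.coords[:, 1], m),
            "gene": np.tile(present, n),
            "value": vals.ravel(),
        }
    )
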