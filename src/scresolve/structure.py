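"""Post-clustering structure summaries.

Two views of an annotated clustering are produced here: a Ward
dendrogram over cluster centroid expression profiles (how the cell
types relate transcriptionally) and a per-condition composition table
(how cell-type frequencies shift, e.g. between control and wounded
skin).

Ward's method merges, at each step, the pair of clusters whose union
minimally increases the total within-cluster sum of squares.  It is run
here via the Lance–Williams recurrence on squared Euclidean
inter-cluster distances,

    d(k, i∪j)^2 = [(n_i+n_k) d(i,k)^2 + (n_j+n_k) d(j,k)^2 − n_k d(i,j)^2]
                  / (n_i + n_j + n_k),

with merge heights reported on the Euclidean-distance scale (singleton
pairs merge at their plain Euclidean distance).  Ties in the minimum
distance are broken toward the lowest (i, j) index pair so results are
deterministic.  Average linkage is not implemented (config stub only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Dendrogram",
    "CompositionTable",
    "ward_dendrogram",
    "dendrogram_to_newick",
    "cluster_centroids",
    "composition_compare",
]


@dataclass
class Dendrogram:
    """Rooted binary merge tree over leaf clusters.

    ``merges`` is an ordered list of (node_a, node_b, height) triples;
    leaves are nodes 0..n-1 and merge m creates node n+m (scipy linkage
    convention).  Heights are non-decreasing for Ward linkage.
    """

    merges: list[tuple[int, int, float]]
    leaf_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_names)
        if len(self.merges) != n - 1:
            raise ValueError("a binary dendrogram over n leaves has n-1 merges")
        used = set()
        for a, b, _h in self.merges:
            for node in (a, b):
                if node in used:
                    raise ValueError(f"node {node} used twice as a child")
                used.add(node)
        heights = [h for _, _, h in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")


@dataclass
class CompositionTable:
    """Counts and within-condition percentages per (condition, cell type)."""

    table: pd.DataFrame  # columns: condition, cell_type, count, percent
    conditions: list[str]


def ward_dendrogram(centroids: np.ndarray, leaf_names: list[str]) -> Dendrogram:
    """Agglomerate cluster centroids under the Ward objective."""
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[0] != len(leaf_names):
        raise ValueError("centroids must be (n_leaves x n_features) aligned to leaf_names")
    n = centroids.shape[0]
    if n < 2:
        raise ValueError("need at least 2 clusters for a dendrogram")
    if not np.all(np.isfinite(centroids)):
        raise ValueError("centroids contain non-finite values")

    d2 = squareform(pdist(centroids, metric="sqeuclidean")) if n > 1 else np.zeros((1, 1))
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    node_of = {i: i for i in range(n)}  # active slot -> dendrogram node id
    merges: list[tuple[int, int, float]] = []
    next_node = n
    D2 = {}
    for ai in range(len(active)):
        for aj in range(ai + 1, len(active)):
            D2[(active[ai], active[aj])] = d2[active[ai], active[aj]]

    def get(i: int, j: int) -> float:
        return D2[(i, j) if i < j else (j, i)]

    members = set(range(n))
    for _ in range(n - 1):
        best = None
        for i in sorted(members):
            for j in sorted(members):
                if j <= i:
                    continue
                v = get(i, j)
                if best is None or v < best[0] - 1e-15 or (abs(v - best[0]) <= 1e-15 and (i, j) < best[1:]):
                    best = (v, i, j)
        _, i, j = best
        height = float(np.sqrt(max(get(i, j), 0.0)))
        merges.append((node_of[i], node_of[j], height))
        ni, nj = sizes[i], sizes[j]
        # Lance–Williams update into slot i
        for k in sorted(members):
            if k in (i, j):
                continue
            nk = sizes[k]
            new = ((ni + nk) * get(i, k) + (nj + nk) * get(j, k) - nk * get(i, j)) / (
                ni + nj + nk
            )
            D2[(i, k) if i < k else (k, i)] = new
        members.remove(j)
        sizes[i] = ni + nj
        node_of[i] = next_node
        next_node += 1
    return Dendrogram(merges=merges, leaf_names=list(leaf_names))


def _newick_name(name: str) -> str:
    if any(ch in name for ch in " \t()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def dendrogram_to_newick(d: Dendrogram) -> str:
    """Serialize to Newick; branch length = parent height − child height
    (leaves sit at height 0, making the tree ultrametric)."""
    n = len(d.leaf_names)
    height = {i: 0.0 for i in range(n)}
    subtree = {i: _newick_name(d.leaf_names[i]) for i in range(n)}
    for m, (a, b, h) in enumerate(d.merges):
        node = n + m
        la, lb = h - height[a], h - height[b]
        subtree[node] = f"({subtree[a]}:{la:.10g},{subtree[b]}:{lb:.10g})"
        height[node] = h
    return subtree[n + len(d.merges) - 1] + ";"


def cluster_centroids(
    norm: np.ndarray, labels: np.ndarray, names: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Per-cluster mean profile of a genes x cells matrix (features on rows
    of the result are the matrix's rows)."""
    labels = np.asarray(labels)
    ks = np.unique(labels)
    cents = np.stack([norm[:, labels == c].mean(axis=1) for c in ks], axis=0)
    if names is None:
        names = [str(int(c)) for c in ks]
    return cents, list(names)


def composition_compare(
    cell_types: list[str] | np.ndarray,
    conditions: list[str] | np.ndarray,
) -> CompositionTable:
    """Counts and percentages of each cell type within each condition.

    Conditions are ordered by first appearance; cell types by descending
    pooled abundance (ties alphabetically).  Types absent in a condition
    are reported with count 0 / percent 0.  An empty condition produces
    zero rows plus a warning.
    """
    ct = np.asarray(cell_types, dtype=object)
    cond = np.asarray(conditions, dtype=object)
    if ct.shape != cond.shape:
        raise ValueError(
            f"cell_types ({ct.size}) and conditions ({cond.size}) are not aligned"
        )
    cond_order = list(dict.fromkeys(cond.tolist()))
    pooled = pd.Series(ct).value_counts()
    type_order = sorted(pooled.index, key=lambda t: (-pooled[t], t))

    rows = []
    for c in cond_order:
        in_c = cond == c
        total = int(in_c.sum())
        if total == 0:
            warnings.warn(f"condition {c!r} has no cells", stacklevel=2)
            continue
        counts = pd.Series(ct[in_c]).value_counts()
        for t in type_order:
            cnt = int(counts.get(t, 0))
            rows.append(
                {
                    "condition": c,
                    "cell_type": t,
                    "count": cnt,
                    "percent": 100.0 * cnt / total,
                }
            )
    table = pd.DataFrame(rows, columns=["condition", "cell_type", "count", "percent"])
    return CompositionTable(table=table, conditions=cond_order)
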