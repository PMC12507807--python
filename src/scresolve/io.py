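"""Readers and writers for the standard on-disk formats.

Counts come in as a 10x-style Matrix Market triplet directory
(``matrix.mtx[.gz]`` + ``features.tsv[.gz]`` + ``barcodes.tsv[.gz]``) or
as a dense CSV/TSV with genes on rows and a header of cell ids.  All
other artifacts (QC report, sweep result, partition, composition,
dendrogram) are plain TSV/JSON/Newick text.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import IO, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import CountMatrix, Partition, SweepResult
from .preprocess import PreprocessReport, ensure_mito_mask
from .structure import CompositionTable, Dendrogram

__all__ = [
    "read_10x_mtx",
    "write_10x_mtx",
    "read_dense_counts",
    "read_partition_tsv",
    "write_partition_tsv",
    "write_preprocess_report",
    "write_sweep_result",
    "write_composition_table",
    "write_dendrogram",
]


def _open_maybe_gz(path: Path) -> IO:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find(dirpath: Path, stem: str) -> Path:
    for cand in (dirpath / stem, dirpath / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing {stem}[.gz] in {dirpath}")


def read_10x_mtx(directory: str | Path, mito_prefix: Optional[str] = None) -> CountMatrix:
    """Read a 10x Matrix Market triplet directory into a CountMatrix.

    ``features.tsv`` may have 1+ columns; the second column (gene
    symbol), when present, names the genes, otherwise the first.
    Mitochondrial genes are flagged by symbol prefix (default ``mt-``,
    case-insensitive).
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    try:
        feat_path = _find(directory, "features.tsv")
    except FileNotFoundError:
        feat_path = _find(directory, "genes.tsv")  # older 10x layout
    bc_path = _find(directory, "barcodes.tsv")

    with (gzip.open(mtx_path, "rb") if mtx_path.suffix == ".gz" else open(mtx_path, "rb")) as fh:
        mat = scipy.io.mmread(fh)
    values = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    symbols = feats.iloc[:, 1] if feats.shape[1] >= 2 else feats.iloc[:, 0]
    gene_ids = symbols.tolist()
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    mito = ensure_mito_mask(gene_ids, None) if mito_prefix is None else np.array(
        [g.lower().startswith(mito_prefix.lower()) for g in gene_ids]
    )
    return CountMatrix(values=values, gene_ids=gene_ids, cell_ids=barcodes, mito_mask=mito)


def write_10x_mtx(counts: CountMatrix, directory: str | Path) -> list[Path]:
    """Write matrix.mtx + features.tsv + barcodes.tsv (uncompressed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx = directory / "matrix.mtx"
    sparse = scipy.sparse.coo_matrix(counts.values)
    scipy.io.mmwrite(str(mtx), sparse, field="integer")
    feats = directory / "features.tsv"
    with open(feats, "w") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    bcs = directory / "barcodes.tsv"
    with open(bcs, "w") as fh:
        fh.write("\n".join(counts.cell_ids) + "\n")
    return [mtx, feats, bcs]


def read_dense_counts(path: str | Path, sep: Optional[str] = None) -> CountMatrix:
    """Dense counts with genes as rows; header row holds cell ids and the
    first column holds gene symbols."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    gene_ids = [str(g) for g in df.index]
    return CountMatrix(
        values=df.to_numpy(),
        gene_ids=gene_ids,
        cell_ids=[str(c) for c in df.columns],
        mito_mask=ensure_mito_mask(gene_ids, None),
    )


def write_partition_tsv(partition: Partition, path: str | Path) -> None:
    cell_ids = partition.cell_ids or [str(i) for i in range(partition.n_cells)]
    with open(path, "w") as fh:
        fh.write("cell_id\tcluster\n")
        for cid, lab in zip(cell_ids, partition.labels):
            fh.write(f"{cid}\t{int(lab)}\n")


def read_partition_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "cluster": int})
    if not {"cell_id", "cluster"} <= set(df.columns):
        raise ValueError("partition TSV needs columns: cell_id, cluster")
    return df


def write_preprocess_report(report: PreprocessReport, prefix: str | Path) -> list[Path]:
    """Per-cell TSV + JSON summary, at <prefix>.per_cell.tsv / <prefix>.json."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".per_cell.tsv")
    report.per_cell.to_csv(tsv, sep="\t", index=False)
    js = prefix.with_suffix(".json")
    js.write_text(json.dumps(report.to_json_summary(), indent=2, sort_keys=True) + "\n")
    return [tsv, js]


def write_sweep_result(result: SweepResult, out_dir: str | Path) -> list[Path]:
    from .sweep import sweep_result_to_json, sweep_result_to_tsv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    js = out_dir / "sweep.json"
    js.write_text(sweep_result_to_json(result) + "\n")
    tsv = out_dir / "sweep.tsv"
    tsv.write_text(sweep_result_to_tsv(result))
    part = out_dir / "partition.tsv"
    write_partition_tsv(result.optimal_partition, part)
    return [js, tsv, part]


def write_composition_table(table: CompositionTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def write_dendrogram(d: Dendrogram, prefix: str | Path) -> list[Path]:
    """Newick at <prefix>.nwk and a merge table at <prefix>.merges.tsv."""
    from .structure import dendrogram_to_newick

    prefix = Path(prefix)
    nwk = prefix.with_suffix(".nwk")
    nwk.write_text(dendrogram_to_newick(d) + "\n")
    tsv = prefix.with_suffix(".merges.tsv")
    with open(tsv, "w") as fh:
        fh.write("node_a\tnode_b\theight\n")
        for a, b, h in d.merges:
            fh.write(f"{a}\t{b}\t{h!r}\n")
    return [nwk, tsv]
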