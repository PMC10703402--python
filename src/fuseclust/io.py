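"""Reading and writing count matrices and run outputs.

Supported input formats (cells in rows throughout):

- dense CSV/TSV: first column cell identifiers, header row gene names;
- MatrixMarket MTX triplet: matrix file plus one-per-line cell and gene name
  text files (rows of the matrix are cells);
- h5ad: an AnnData container, ``X`` taken as raw counts.

Labels are a two-column CSV (cell id, label).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocess import RawCountMatrix

__all__ = ["read_counts", "read_labels", "write_mtx", "write_run_outputs"]


class FormatError(ValueError):
    """Unrecognised or malformed input."""


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".csv", ".tsv", ".txt"}:
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".h5ad":
        return "h5ad"
    raise FormatError(f"cannot infer format from {path.name!r}; pass format=")


def read_counts(path, fmt: str | None = None, cells_file=None, genes_file=None,
                labels_file=None) -> RawCountMatrix:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, index_col=0, sep=sep)
        counts = df.to_numpy()
        raw = RawCountMatrix(counts=counts,
                             cell_ids=[str(c) for c in df.index],
                             gene_ids=[str(g) for g in df.columns])
    elif fmt == "mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        cells_file = Path(cells_file) if cells_file else path.with_name("barcodes.tsv")
        genes_file = Path(genes_file) if genes_file else path.with_name("genes.tsv")
        cell_ids = cells_file.read_text().split() if cells_file.exists() else []
        gene_ids = genes_file.read_text().split() if genes_file.exists() else []
        raw = RawCountMatrix(counts=np.asarray(mat), cell_ids=cell_ids,
                             gene_ids=gene_ids)
    elif fmt == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        x = adata.X
        if sparse.issparse(x):
            x = x.toarray()
        raw = RawCountMatrix(counts=np.asarray(x),
                             cell_ids=[str(c) for c in adata.obs_names],
                             gene_ids=[str(g) for g in adata.var_names])
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if labels_file is not None:
        raw.labels = read_labels(labels_file, raw.cell_ids)
    return raw


def read_labels(path, cell_ids: list[str] | None = None) -> np.ndarray:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("labels CSV needs two columns: cell id, label")
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1]))
    if cell_ids is None:
        return df.iloc[:, 1].to_numpy()
    return np.array([mapping[str(c)] for c in cell_ids])


def write_mtx(outdir, raw: RawCountMatrix) -> dict:
    """Write counts as MTX triplet (matrix.mtx, barcodes.tsv, genes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx = outdir / "matrix.mtx"
    spio.mmwrite(mtx, sparse.coo_matrix(np.asarray(raw.counts)))
    (outdir / "barcodes.tsv").write_text("\n".join(raw.cell_ids) + "\n")
    (outdir / "genes.tsv").write_text("\n".join(raw.gene_ids) + "\n")
    return {"matrix": mtx, "barcodes": outdir / "barcodes.tsv",
            "genes": outdir / "genes.tsv"}


def write_run_outputs(outdir, est, report: dict,
                      export_attention: bool = False) -> None:
    """Persist labels, embedding, cluster-count trajectory and JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": est.cell_ids_, "cluster": est.labels_}
                 ).to_csv(outdir / "labels.csv", index=False)
    emb = pd.DataFrame(est.embedding_, index=est.cell_ids_)
    emb.index.name = "cell_id"
    emb.to_csv(outdir / "embedding.csv")
    pd.DataFrame({"checkpoint": range(len(est.cluster_count_trajectory_)),
                  "n_clusters": est.cluster_count_trajectory_}
                 ).to_csv(outdir / "cluster_count_trajectory.csv", index=False)
    if export_attention and est.attention_scores_ is not None:
        for b, scores in enumerate(est.attention_scores_, start=1):
            for h in range(scores.shape[0]):
                np.savetxt(outdir / f"attention_block{b}_head{h}.csv",
                           scores[h], delimiter=",")
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
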