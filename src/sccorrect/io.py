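"""Reading and writing the standard on-disk formats.

Datasets enter as MatrixMarket MTX (features x cells, 10x convention)
with sidecar features/barcodes TSVs, or as dense CSV with cells as rows.
Peak coordinates are BED (0-based half-open); TSS tables are TSV with
columns gene, chrom, tss, strand.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .preprocess import ExpressionDataset

__all__ = [
    "read_mtx_dir",
    "read_dense_csv",
    "read_bed",
    "write_mtx_dir",
    "write_embedding_tsv",
]


def read_mtx_dir(path, batch_id: str) -> ExpressionDataset:
    """Read matrix.mtx + features.tsv + barcodes.tsv from a directory.

    The matrix is stored features x cells (the common exchange layout)
    and transposed to cells x features on load.
    """
    path = Path(path)
    matrix = scipy.io.mmread(path / "matrix.mtx").tocsr()
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    return ExpressionDataset(
        values=matrix.T.tocsr(),
        cell_ids=barcodes,
        feature_ids=features,
        batch_id=batch_id,
    )


def write_mtx_dir(ds: ExpressionDataset, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(ds.values.T))
    pd.Series(ds.feature_ids).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(ds.cell_ids).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_dense_csv(path, batch_id: str) -> ExpressionDataset:
    """Read a dense CSV with cells as rows and features as columns."""
    df = pd.read_csv(path, index_col=0)
    return ExpressionDataset(
        values=sp.csr_matrix(df.to_numpy(dtype=float)),
        cell_ids=[str(c) for c in df.index],
        feature_ids=[str(f) for f in df.columns],
        batch_id=batch_id,
    )


def read_bed(path) -> pd.DataFrame:
    """Read a BED file of peak intervals into (chrom, start, end, name)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df


def write_embedding_tsv(embedding, path) -> None:
    embedding.to_frame().to_csv(path, sep="\t", index=False)


def read_embedding_tsv(path):
    df = pd.read_csv(path, sep="\t")
    coord_cols = [c for c in df.columns if c.startswith("L")]
    return (
        df[coord_cols].to_numpy(dtype=float),
        df["cell_id"].tolist(),
        df["batch"].astype(str).tolist(),
    )
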