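"""Quality control, normalization, variable-feature selection, and scATAC gene scoring.

Raw inputs are cells x features count matrices (one per batch/dataset).
scRNA-seq data are library-size normalized and log-transformed before
highly variable genes (HVGs) are selected by a binned, z-scored Fano
factor.  scATAC-seq peak matrices are first converted to a genes x cells
activity matrix by summing peak counts near each gene's transcription
start site with exponentially decaying weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "FeatureMatrix",
    "TssTable",
    "filter_qc",
    "normalize",
    "select_hvg",
    "gene_scoring",
    "intersect_features",
]


def _as_spmatrix(values) -> sp.csr_matrix:
    if sp.issparse(values):
        return values.tocsr()
    return sp.csr_matrix(np.asarray(values, dtype=float))


@dataclass
class ExpressionDataset:
    """A cells x features matrix of nonnegative values with a batch identity.

    ``values`` may be dense or scipy-sparse; it is stored as CSR.  Cell and
    feature identifiers must be unique within the dataset.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    batch_id: str

    def __post_init__(self):
        self.values = _as_spmatrix(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, m = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(f"{n} rows but {len(self.cell_ids)} cell ids")
        if m != len(self.feature_ids):
            raise ValueError(f"{m} columns but {len(self.feature_ids)} feature ids")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.feature_ids)) != m:
            raise ValueError("duplicate feature ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("expression values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=float)


@dataclass
class FeatureMatrix:
    """Log-normalized expression restricted to a common HVG feature space.

    Rows are cells, columns the m selected features; the feature set and
    column order are identical across all datasets entering integration.
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    batch_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(
            self.values.todense() if sp.issparse(self.values) else self.values,
            dtype=float,
        )
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length mismatch")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length mismatch")
        if not self.batch_ids:
            self.batch_ids = [""] * self.values.shape[0]
        if len(self.batch_ids) != self.values.shape[0]:
            raise ValueError("batch_ids length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class TssTable:
    """Transcription start sites: one row per gene (gene, chrom, tss, strand)."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"gene", "chrom", "tss", "strand"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"TSS table missing columns: {sorted(missing)}")
        if self.table["gene"].duplicated().any():
            raise ValueError("TSS table has duplicate genes")
        if (self.table["tss"] < 0).any():
            raise ValueError("TSS positions must be nonnegative")

    @classmethod
    def from_tsv(cls, path) -> "TssTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def filter_qc(
    ds: ExpressionDataset, min_cells: int = 3, min_features: int = 200
) -> ExpressionDataset:
    """Remove rarely detected features, then sparsely covered cells.

    A feature is kept if it is nonzero in at least ``min_cells`` cells; a
    cell is kept if, after feature filtering, it has at least
    ``min_features`` nonzero features.  Single pass: features first, then
    cells, no iteration.
    """
    if ds.n_cells == 0 or ds.n_features == 0:
        raise ValueError("empty dataset")
    nonzero = ds.values.copy()
    nonzero.data = np.ones_like(nonzero.data)
    cells_per_feature = np.asarray(nonzero.sum(axis=0)).ravel()
    keep_features = cells_per_feature >= min_cells
    if not keep_features.any():
        raise ValueError(
            f"no features survive QC in dataset {ds.batch_id!r} "
            f"(min_cells={min_cells})"
        )
    filtered = ds.values[:, keep_features]
    nz = filtered.copy()
    nz.data = np.ones_like(nz.data)
    features_per_cell = np.asarray(nz.sum(axis=1)).ravel()
    keep_cells = features_per_cell >= min_features
    if not keep_cells.any():
        raise ValueError(
            f"no cells survive QC in dataset {ds.batch_id!r} "
            f"(min_features={min_features})"
        )
    return ExpressionDataset(
        values=filtered[keep_cells],
        cell_ids=[c for c, k in zip(ds.cell_ids, keep_cells) if k],
        feature_ids=[f for f, k in zip(ds.feature_ids, keep_features) if k],
        batch_id=ds.batch_id,
    )


def normalize(ds: ExpressionDataset, scale_factor: float = 10_000.0) -> ExpressionDataset:
    """Library-size normalize and log-transform.

    out[c, g] = ln(1 + scale_factor * x[c, g] / total(c)) with total(c) the
    cell's summed counts.  The zero pattern is preserved.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = np.asarray(ds.values.sum(axis=1)).ravel()
    zero_total = np.flatnonzero(totals == 0)
    if zero_total.size:
        names = [ds.cell_ids[i] for i in zero_total[:5]]
        raise ValueError(f"cells with zero total counts: {names}")
    out = ds.values.astype(float).tocsr(copy=True)
    row_of = np.repeat(np.arange(ds.n_cells), np.diff(out.indptr))
    out.data = np.log1p(scale_factor * out.data / totals[row_of])
    return replace(ds, values=out)


def select_hvg(
    norm: ExpressionDataset,
    n_bins: int = 20,
    fano_threshold: float = 0.05,
    mean_threshold: float = 0.01,
) -> list[str]:
    """Select highly variable genes by binned, z-scored Fano factor.

    Per-gene mean and Fano factor (variance/mean) are computed on the
    log-normalized matrix; genes are ranked by mean expression and split
    into ``n_bins`` equal-count bins; within each bin the Fano factors are
    z-scored.  Genes with z-scored Fano > ``fano_threshold`` and mean >
    ``mean_threshold`` are returned, sorted by descending normalized Fano.
    """
    x = norm.values
    n = x.shape[0]
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = x.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = np.maximum(ex2 - mean**2, 0.0) * (n / max(n - 1, 1))
    expressed = mean > 0
    idx = np.flatnonzero(expressed)
    if idx.size == 0:
        return []
    fano = var[idx] / mean[idx]
    bins = min(n_bins, idx.size)
    if bins < n_bins:
        warnings.warn(
            f"only {idx.size} expressed genes; reducing bin count to {bins}",
            stacklevel=2,
        )
    # equal-count bins over genes sorted by mean; ties broken by gene order
    order = np.argsort(mean[idx], kind="stable")
    bin_groups = np.array_split(order, bins)
    z = np.full(idx.size, np.nan)
    for members in bin_groups:
        f = fano[members]
        sd = f.std()
        z[members] = 0.0 if sd == 0 else (f - f.mean()) / sd
    selected = (z > fano_threshold) & (mean[idx] > mean_threshold)
    chosen = idx[selected]
    ranking = np.argsort(-z[selected], kind="stable")
    return [norm.feature_ids[g] for g in chosen[ranking]]


def gene_scoring(
    peaks: ExpressionDataset,
    peak_coords: pd.DataFrame,
    tss: TssTable,
    window: int = 50_000,
    decay_scale: float = 5_000.0,
) -> ExpressionDataset:
    """Convert a peaks-by-cells accessibility matrix into gene activity scores.

    Each gene accumulates the counts of peaks whose midpoint lies within
    ``window`` bp of its TSS, weighted by exp(-distance / decay_scale).
    ``peak_coords`` is BED-style (chrom, start, end, name) with 0-based
    half-open intervals; ``name`` must match the peak feature ids.

    Genes with no in-window peak receive all-zero rows.
    """
    coords = peak_coords.set_index("name")
    missing = [p for p in peaks.feature_ids if p not in coords.index]
    if missing:
        raise ValueError(f"peaks without coordinates: {missing[:10]}")
    coords = coords.loc[peaks.feature_ids]
    mid = (coords["start"].to_numpy() + coords["end"].to_numpy()) / 2.0
    chrom = coords["chrom"].to_numpy()

    genes = tss.table["gene"].tolist()
    rows, cols, weights = [], [], []
    for gi, (g_chrom, g_tss) in enumerate(
        zip(tss.table["chrom"].to_numpy(), tss.table["tss"].to_numpy())
    ):
        on_chrom = np.flatnonzero(chrom == g_chrom)
        if on_chrom.size == 0:
            continue
        dist = np.abs(mid[on_chrom] - g_tss)
        close = dist <= window
        for pi, d in zip(on_chrom[close], dist[close]):
            rows.append(pi)
            cols.append(gi)
            weights.append(np.exp(-d / decay_scale))
    w = sp.csr_matrix(
        (weights, (rows, cols)), shape=(peaks.n_features, len(genes))
    )
    scores = peaks.values @ w
    return ExpressionDataset(
        values=scores,
        cell_ids=peaks.cell_ids,
        feature_ids=genes,
        batch_id=peaks.batch_id,
    )


def intersect_features(
    datasets: list[ExpressionDataset], hvg_per_dataset: list[list[str]]
) -> list[FeatureMatrix]:
    """Restrict all datasets to a common HVG feature space.

    The shared features are the union of the per-dataset HVG lists,
    intersected with the features present in every dataset, in stable
    first-appearance order.  Input datasets must already be normalized.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    if len(hvg_per_dataset) != len(datasets):
        raise ValueError("one HVG list per dataset required")
    present_everywhere = set(datasets[0].feature_ids)
    for ds in datasets[1:]:
        present_everywhere &= set(ds.feature_ids)
    shared: list[str] = []
    seen: set[str] = set()
    for hvgs in hvg_per_dataset:
        for g in hvgs:
            if g in present_everywhere and g not in seen:
                seen.add(g)
                shared.append(g)
    if not shared:
        raise ValueError("no shared variable features across datasets")
    out = []
    for ds in datasets:
        col = {f: j for j, f in enumerate(ds.feature_ids)}
        sub = ds.values[:, [col[g] for g in shared]]
        out.append(
            FeatureMatrix(
                values=np.asarray(sub.todense(), dtype=float),
                feature_ids=list(shared),
                cell_ids=list(ds.cell_ids),
                batch_ids=[ds.batch_id] * ds.n_cells,
            )
        )
    return out
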