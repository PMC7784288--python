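"""End-to-end orchestration of the integration pipeline.

``run_integration`` executes the eight stages in order — QC,
normalization, HVG selection, per-dataset consensus clustering,
confident-cell detection, marker-based cluster matching, confounding
matrix assembly, penalized eigendecomposition — and projects all cells
into the shared embedding.  All randomness flows from one master seed;
per-dataset and per-pair seeds are derived from content identities
(batch ids, cluster pair ids), so results do not depend on the order in
which datasets are supplied.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import correct as _correct
from . import match as _match
from . import preprocess as _pre

__all__ = ["RunConfig", "IntegrationResult", "run_integration", "run_project"]


@dataclass
class RunConfig:
    """Tunable parameters of an integration run.

    ``lam`` scales the subtraction of technical variance (0 disables
    correction and yields plain PCA); ``threshold`` is the cluster-pair
    similarity cutoff T; ``quantile_cutoff`` generalizes the
    third-quantile confident-cell rule.
    """

    lam: float = 10.0
    threshold: float = 0.6
    k_vectors: int = 40
    snn_k: int = 20
    n_pcs: int = 40
    resolutions: tuple = _cluster.DEFAULT_RESOLUTIONS
    quantile_cutoff: float = 0.75
    scale_factor: float = 10_000.0
    min_cells: int = 3
    min_features: int = 200
    hvg_bins: int = 20
    hvg_fano_threshold: float = 0.05
    hvg_mean_threshold: float = 0.01
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold T must lie in (0, 1)")
        if not 0.5 <= self.quantile_cutoff < 1:
            raise ValueError("quantile_cutoff must lie in [0.5, 1)")


@dataclass
class IntegrationResult:
    """Everything an integration run produces."""

    embedding: _correct.Embedding
    basis: _correct.CorrectionBasis
    feature_matrices: dict  # batch id -> FeatureMatrix (all cells)
    assignments: dict  # batch id -> ClusterAssignment (with confident flags)
    pairs: _match.SharedPairSet | None
    log: dict = field(default_factory=dict)


def _dataset_seed(master: int, batch_id: str) -> int:
    return (zlib.crc32(str(batch_id).encode()) + int(master)) % (2**31)


def run_integration(
    datasets: list[_pre.ExpressionDataset],
    cfg: RunConfig | None = None,
) -> IntegrationResult:
    """Integrate two or more datasets into a shared corrected embedding."""
    cfg = cfg or RunConfig()
    if len(datasets) < 2:
        raise ValueError("integration needs at least two datasets")
    ids = [ds.batch_id for ds in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("batch ids must be unique across datasets")
    log: dict = {"parameters": {k: str(v) for k, v in vars(cfg).items()}, "stages": {}}

    # 1-2: QC, normalization, HVG selection, shared feature space
    normed, hvgs = [], []
    for ds in datasets:
        try:
            clean = _pre.filter_qc(ds, cfg.min_cells, cfg.min_features)
        except ValueError as e:
            raise ValueError(f"[qc:{ds.batch_id}] {e}") from e
        norm = _pre.normalize(clean, cfg.scale_factor)
        normed.append(norm)
        hvgs.append(
            _pre.select_hvg(
                norm,
                n_bins=cfg.hvg_bins,
                fano_threshold=cfg.hvg_fano_threshold,
                mean_threshold=cfg.hvg_mean_threshold,
            )
        )
    fms = _pre.intersect_features(normed, hvgs)
    log["stages"]["features"] = {
        "n_shared_features": fms[0].n_features,
        "n_cells": {b: fm.n_cells for b, fm in zip(ids, fms)},
    }

    # 3-4: per-dataset consensus clustering and confident cells
    assignments = {}
    for batch_id, fm in zip(ids, fms):
        seed = _dataset_seed(cfg.seed, batch_id)
        g = _cluster.build_snn(fm, k=cfg.snn_k, n_pcs=cfg.n_pcs)
        cons = _cluster.consensus_cluster(g, resolutions=cfg.resolutions, seed=seed)
        conf = _cluster.confident_cells(g, cons.labels, cfg.quantile_cutoff)
        conf.consensus = cons.consensus
        assignments[batch_id] = conf
    log["stages"]["clustering"] = {
        b: {
            "n_clusters": a.n_clusters,
            "n_confident": int(a.confident.sum()),
        }
        for b, a in assignments.items()
    }

    # 5: markers and shared cluster pairs
    match_input = {}
    for batch_id, fm in zip(ids, fms):
        a = assignments[batch_id]
        markers = {}
        for cid in np.unique(a.labels):
            try:
                markers[int(cid)] = _match.find_markers(
                    fm, a.labels, a.confident, int(cid)
                )
            except ValueError as e:
                warnings.warn(
                    f"[markers:{batch_id}:{cid}] {e}; treating cluster as markerless",
                    stacklevel=2,
                )
                markers[int(cid)] = _match.MarkerSet(
                    cluster_id=int(cid),
                    markers=pd.DataFrame(
                        columns=["feature", "p_value", "log_fc", "pct_in", "pct_out"]
                    ),
                )
        match_input[batch_id] = {
            "fm": fm,
            "labels": a.labels,
            "confident": a.confident,
            "markers": markers,
        }
    pair_set = _match.shared_pairs(match_input, threshold=cfg.threshold)
    log["stages"]["pairs"] = {
        "n_edges": len(pair_set.edges),
        "n_shared": len(pair_set.pairs),
    }

    # 6-7: confounding matrix and correction vectors on the confident stack
    conf_rows, conf_keys, conf_cells, conf_batches = [], [], [], []
    for batch_id, fm in zip(ids, fms):
        a = assignments[batch_id]
        take = np.flatnonzero(a.confident)
        conf_rows.append(fm.values[take])
        conf_keys.extend((batch_id, int(a.labels[i])) for i in take)
        conf_cells.extend(fm.cell_ids[i] for i in take)
        conf_batches.extend([batch_id] * take.size)
    x_hat = _pre.FeatureMatrix(
        values=np.vstack(conf_rows),
        feature_ids=fms[0].feature_ids,
        cell_ids=conf_cells,
        batch_ids=conf_batches,
    )
    if len(pair_set.pairs) == 0:
        warnings.warn(
            "no cluster pair exceeds the similarity threshold; no technical "
            "variation can be inferred — falling back to an uncorrected PCA "
            "embedding (lambda = 0)",
            stacklevel=2,
        )
        confounding = None
        basis = _correct.learn_correction(x_hat, None, lam=0.0, k=cfg.k_vectors)
    else:
        confounding = _correct.build_confounding(
            x_hat, pair_set, conf_keys, seed=cfg.seed
        )
        basis = _correct.learn_correction(
            x_hat, confounding, lam=cfg.lam, k=cfg.k_vectors
        )
    log["stages"]["correction"] = {
        "k": basis.k,
        "lambda": basis.lam,
        "technical_ratio": basis.R,
        "n_confounding_columns": 0 if confounding is None else confounding.n_columns,
    }

    # 8: project all cells
    x_all = _pre.FeatureMatrix(
        values=np.vstack([fm.values for fm in fms]),
        feature_ids=fms[0].feature_ids,
        cell_ids=[c for fm in fms for c in fm.cell_ids],
        batch_ids=[b for fm in fms for b in fm.batch_ids],
    )
    embedding = _correct.project(x_all, basis)
    result = IntegrationResult(
        embedding=embedding,
        basis=basis,
        feature_matrices=dict(zip(ids, fms)),
        assignments=assignments,
        pairs=pair_set,
        log=log,
    )
    if cfg.output_dir is not None:
        _persist(result, cfg)
    return result


def run_project(
    basis: _correct.CorrectionBasis | str | Path,
    new_dataset: _pre.ExpressionDataset,
    cfg: RunConfig | None = None,
) -> _correct.Embedding:
    """Project a new dataset into an existing shared embedding.

    The new dataset is QC-filtered, normalized with the same scale
    factor, matched by feature id to the basis feature space (missing
    features zero-filled) and projected with the stored centering vector
    and correction vectors.
    """
    cfg = cfg or RunConfig()
    if not isinstance(basis, _correct.CorrectionBasis):
        basis = _correct.CorrectionBasis.load(basis)
    if new_dataset.n_cells == 0:
        raise ValueError("new dataset has no cells")
    clean = _pre.filter_qc(new_dataset, cfg.min_cells, cfg.min_features)
    norm = _pre.normalize(clean, cfg.scale_factor)
    fm = _pre.FeatureMatrix(
        values=np.asarray(norm.values.todense(), dtype=float),
        feature_ids=list(norm.feature_ids),
        cell_ids=list(norm.cell_ids),
        batch_ids=[norm.batch_id] * norm.n_cells,
    )
    return _correct.project_new(fm, basis)


def _persist(result: IntegrationResult, cfg: RunConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.embedding.to_frame().to_csv(out / "embedding.tsv", sep="\t", index=False)
    rows = []
    for batch_id, a in result.assignments.items():
        fm = result.feature_matrices[batch_id]
        for i, cell in enumerate(fm.cell_ids):
            rows.append(
                (
                    cell,
                    batch_id,
                    int(a.labels[i]),
                    bool(a.confident[i]),
                    float(a.avg_similarity[i]),
                )
            )
    pd.DataFrame(
        rows, columns=["cell_id", "batch", "cluster", "confident", "avg_similarity"]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    if result.pairs is not None:
        result.pairs.edges.to_csv(out / "pairs.tsv", sep="\t", index=False)
    result.basis.save(out / "basis.npz")
    with open(out / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2, default=str)
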