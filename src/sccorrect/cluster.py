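"""Per-dataset consensus clustering on a shared-nearest-neighbor graph.

Each dataset is clustered separately: PCA, kNN in PC space, SNN edge
weights from shared-neighbor fractions, Leiden partitions over a grid of
resolutions, a consensus co-clustering matrix, an SVD-based estimate of
the cluster number, and an average-linkage cut of the consensus matrix.
Confident cells — those most similar to the rest of their cluster — are
flagged with the third-quantile rule and later drive cluster matching and
correction learning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SNNGraph",
    "ClusterAssignment",
    "build_snn",
    "leiden_once",
    "consensus_cluster",
    "estimate_n_clusters",
    "confident_cells",
]

DEFAULT_RESOLUTIONS = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class SNNGraph:
    """Shared-nearest-neighbor graph: weight(i,j) = |NN(i) ∩ NN(j)| / k."""

    weights: sp.csr_matrix  # symmetric, zero diagonal, entries in (0, 1]
    k: int
    n_pcs: int

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    def edges(self) -> list[tuple[int, int, float]]:
        coo = sp.triu(self.weights, k=1).tocoo()
        return list(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))


@dataclass
class ClusterAssignment:
    """Consensus clustering result for one dataset."""

    labels: np.ndarray  # integer cluster per cell, 1..n_clusters
    consensus: np.ndarray  # n x n co-clustering frequencies
    n_clusters: int
    confident: np.ndarray = field(default=None)  # bool per cell
    avg_similarity: np.ndarray = field(default=None)  # mean within-cluster SNN weight


def build_snn(fm, k: int = 20, n_pcs: int = 40) -> SNNGraph:
    """Build the SNN graph from PCA coordinates of a feature matrix.

    PCA is computed on the column-centered (not scaled) matrix; the k
    nearest neighbors (Euclidean, excluding self) define, for every cell
    pair, an edge weighted by the fraction |NN(i) ∩ NN(j)| / k of shared
    neighbors.  Zero-weight pairs carry no edge.
    """
    x = np.asarray(fm.values, dtype=float)
    n = x.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n}")
    n_pcs = min(n_pcs, min(x.shape) - 1)
    xc = x - x.mean(axis=0)
    # PCA via thin SVD; deterministic sign for reproducibility
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    neigh = idx[:, 1:]  # drop self
    a = sp.csr_matrix(
        (np.ones(n * k), (np.repeat(np.arange(n), k), neigh.ravel())),
        shape=(n, n),
    )
    shared = (a @ a.T) / k  # entry (i,j) = |NN(i) ∩ NN(j)| / k
    shared.setdiag(0)
    shared.eliminate_zeros()
    return SNNGraph(weights=shared.tocsr(), k=k, n_pcs=n_pcs)


def snn_jaccard(g: SNNGraph) -> SNNGraph:
    """Rescale SNN weights from |∩|/k to Jaccard |∩|/|∪| = |∩|/(2k - |∩|)."""
    w = g.weights.copy()
    inter = w.data * g.k
    w.data = inter / (2 * g.k - inter)
    return SNNGraph(weights=w, k=g.k, n_pcs=g.n_pcs)


def _to_igraph(g: SNNGraph) -> igraph.Graph:
    coo = sp.triu(g.weights, k=1).tocoo()
    graph = igraph.Graph(
        n=g.n_cells, edges=list(zip(coo.row.tolist(), coo.col.tolist()))
    )
    graph.es["weight"] = coo.data.tolist()
    return graph


def leiden_once(g: SNNGraph, resolution: float, seed: int) -> np.ndarray:
    """One Leiden run at the given resolution; deterministic for a fixed seed."""
    graph = _to_igraph(g)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if graph.ecount() else None,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=int)


def estimate_n_clusters(consensus: np.ndarray, ratio_threshold: float = 0.01) -> int:
    """Estimate the cluster count from the consensus matrix spectrum.

    Returns the number of singular values whose share of the total
    singular-value mass exceeds ``ratio_threshold``, clamped to
    [1, n_cells].
    """
    c = np.asarray(consensus, dtype=float)
    svals = np.linalg.svd(c, compute_uv=False)
    total = svals.sum()
    if total == 0:
        return 1
    count = int(np.sum(svals / total > ratio_threshold))
    return int(np.clip(count, 1, c.shape[0]))


def consensus_cluster(
    g: SNNGraph,
    resolutions=DEFAULT_RESOLUTIONS,
    seed: int = 0,
    ratio_threshold: float = 0.01,
) -> ClusterAssignment:
    """Consensus Leiden clustering over a grid of resolutions.

    The consensus matrix holds the fraction of resolutions at which each
    cell pair co-clusters; its spectrum sets the cluster number and an
    average-linkage cut of 1 - consensus yields the final labels
    (1..n_clusters).  Per-resolution Leiden seeds derive deterministically
    from the master seed.
    """
    n = g.n_cells
    consensus = np.zeros((n, n))
    for r_idx, res in enumerate(resolutions):
        labels = leiden_once(g, res, seed=seed + r_idx)
        consensus += labels[:, None] == labels[None, :]
    consensus /= len(resolutions)
    n_clusters = estimate_n_clusters(consensus, ratio_threshold)
    if n_clusters == 1:
        labels = np.ones(n, dtype=int)
    else:
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return ClusterAssignment(
        labels=np.asarray(labels, dtype=int),
        consensus=consensus,
        n_clusters=int(labels.max()),
    )


def confident_cells(
    g: SNNGraph,
    labels: np.ndarray,
    quantile_cutoff: float = 0.75,
) -> ClusterAssignment:
    """Flag confident cells: average within-cluster SNN similarity above Q3.

    For each cell, the average similarity is the mean SNN weight to all
    other cells of its cluster (missing edges count as 0).  Within each
    cluster, cells strictly above the ``quantile_cutoff`` quantile
    (default the third quartile) are confident.  Degenerate clusters where
    the strict rule selects nobody (all similarities tied) fall back to
    the top max(3, 10%) cells by average similarity.
    """
    labels = np.asarray(labels, dtype=int)
    n = g.n_cells
    if labels.shape[0] != n:
        raise ValueError("labels length mismatch")
    avg = np.zeros(n)
    confident = np.zeros(n, dtype=bool)
    w = g.weights
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size == 1:
            warnings.warn(
                f"cluster {lab} is a singleton; marking its cell confident",
                stacklevel=2,
            )
            confident[members] = True
            continue
        sub = w[members][:, members]
        avg[members] = np.asarray(sub.sum(axis=1)).ravel() / (members.size - 1)
        q3 = np.percentile(avg[members], 100 * quantile_cutoff)
        sel = avg[members] > q3
        if sel.sum() == 0:
            floor = min(members.size, max(3, int(np.ceil(0.1 * members.size))))
            top = np.argsort(-avg[members], kind="stable")[:floor]
            sel = np.zeros(members.size, dtype=bool)
            sel[top] = True
        confident[members[sel]] = True
    return ClusterAssignment(
        labels=labels,
        consensus=None,
        n_clusters=int(np.unique(labels).size),
        confident=confident,
        avg_similarity=avg,
    )
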