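"""Marker detection and inference of shared clusters across datasets.

Markers of each putative cluster are found on its confident cells with a
two-part (hurdle) likelihood-ratio test that jointly scores a change in
the fraction of expressing cells and a change in mean expression among
expressing cells.  Cluster pairs across datasets are weighted by the
average of a marker-overlap score and the cosine similarity of mean
expression over the marker union; pairs above the threshold T are
declared shared, defining the technical variation to remove.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = ["MarkerSet", "SharedPairSet", "find_markers", "cluster_similarity", "shared_pairs"]


@dataclass
class MarkerSet:
    """Markers of one cluster: (feature, p_value, log_fc, pct_in, pct_out) rows."""

    cluster_id: int
    markers: pd.DataFrame

    @property
    def features(self) -> list[str]:
        return self.markers["feature"].tolist()

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class SharedPairSet:
    """Weighted bipartite cluster graph across datasets and its thresholded pairs.

    ``edges`` holds every cross-dataset cluster pair with its overlap,
    cosine and combined similarity; ``pairs`` is the subset with
    similarity strictly greater than T.  A cluster may take part in more
    than one pair; clusters in no pair are dataset-specific.
    """

    edges: pd.DataFrame
    threshold: float

    @property
    def pairs(self) -> pd.DataFrame:
        return self.edges[self.edges["similarity"] > self.threshold].reset_index(
            drop=True
        )

    def specific_clusters(self, clusters_by_dataset: dict) -> list[tuple[str, int]]:
        """Clusters participating in no shared pair."""
        matched = set()
        for _, row in self.pairs.iterrows():
            matched.add((row["dataset_i"], row["cluster_p"]))
            matched.add((row["dataset_j"], row["cluster_q"]))
        out = []
        for ds, clusters in clusters_by_dataset.items():
            for c in clusters:
                if (ds, c) not in matched:
                    out.append((ds, c))
        return out


def _binomial_deviance(k1: int, n1: int, k2: int, n2: int) -> float:
    """2 * log-LR for equal vs separate Bernoulli expression proportions."""

    def ll(k, n):
        if n == 0:
            return 0.0
        p = k / n
        out = 0.0
        if k > 0:
            out += k * np.log(p)
        if n - k > 0:
            out += (n - k) * np.log(1 - p)
        return out

    return 2.0 * (ll(k1, n1) + ll(k2, n2) - ll(k1 + k2, n1 + n2))


def _normal_deviance(y1: np.ndarray, y2: np.ndarray) -> float:
    """2 * log-LR for equal vs separate normal means (pooled MLE variance)."""
    n1, n2 = y1.size, y2.size
    if n1 == 0 or n2 == 0:
        return 0.0
    n = n1 + n2
    y = np.concatenate([y1, y2])
    rss0 = np.sum((y - y.mean()) ** 2)
    rss1 = np.sum((y1 - y1.mean()) ** 2) + np.sum((y2 - y2.mean()) ** 2)
    if rss0 <= 0:
        return 0.0
    if rss1 <= 0:
        # separate means fit perfectly; deviance is formally unbounded
        return np.inf if rss0 > 0 else 0.0
    return n * np.log(rss0 / rss1)


def find_markers(
    fm,
    labels: np.ndarray,
    confident: np.ndarray,
    cluster_id: int,
    p_threshold: float = 0.05,
    logfc_threshold: float = 0.25,
    pct_threshold: float = 0.25,
) -> MarkerSet:
    """Markers of one cluster via a two-part hurdle likelihood-ratio test.

    Confident cells of the cluster are contrasted with the confident cells
    of all other clusters in the same dataset.  Per feature, the LRT
    statistic is the sum of a binomial deviance (fraction of expressing
    cells) and a conditional-normal deviance (mean of log-expression among
    expressing cells); p-values come from chi-square with 2 df.  Markers
    must satisfy p < 0.05, log fold-change > 0.25 (natural log), and
    in-cluster expression fraction > 25%; ties sort by p then fold-change.
    """
    labels = np.asarray(labels)
    confident = np.asarray(confident, dtype=bool)
    in_mask = confident & (labels == cluster_id)
    out_mask = confident & (labels != cluster_id)
    if in_mask.sum() < 3:
        raise ValueError(f"cluster {cluster_id} has fewer than 3 confident cells")
    if out_mask.sum() == 0:
        raise ValueError("no other clusters to contrast against")
    x_in = fm.values[in_mask]
    x_out = fm.values[out_mask]
    n1, n2 = x_in.shape[0], x_out.shape[0]
    rows = []
    for j, feature in enumerate(fm.feature_ids):
        v1, v2 = x_in[:, j], x_out[:, j]
        e1, e2 = v1 > 0, v2 > 0
        k1, k2 = int(e1.sum()), int(e2.sum())
        pct_in, pct_out = k1 / n1, k2 / n2
        log_fc = v1.mean() - v2.mean()
        if pct_in <= pct_threshold or log_fc <= logfc_threshold:
            continue
        dev = _binomial_deviance(k1, n1, k2, n2) + _normal_deviance(v1[e1], v2[e2])
        p = float(chi2.sf(dev, df=2))
        if p < p_threshold:
            rows.append((feature, p, log_fc, pct_in, pct_out))
    df = pd.DataFrame(
        rows, columns=["feature", "p_value", "log_fc", "pct_in", "pct_out"]
    )
    df = df.sort_values(
        ["p_value", "log_fc"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return MarkerSet(cluster_id=cluster_id, markers=df)


def _mean_profile(fm, labels, confident, cluster_id, features: list[str]) -> np.ndarray:
    idx = {f: j for j, f in enumerate(fm.feature_ids)}
    cols = [idx[f] for f in features]
    mask = np.asarray(confident, dtype=bool) & (np.asarray(labels) == cluster_id)
    return fm.values[np.ix_(mask, cols)].mean(axis=0)


def cluster_similarity(
    markers_p: MarkerSet,
    markers_q: MarkerSet,
    fm_p,
    fm_q,
    labels_p,
    labels_q,
    confident_p,
    confident_q,
) -> tuple[float, float, float]:
    """Similarity of two clusters from different datasets.

    Returns (overlap, cosine, similarity): overlap = |shared markers| /
    min(n1, n2); cosine compares the confident-cell mean expression of the
    two clusters over the union of their markers; similarity is the mean
    of the two.  With markers on only one side the cosine alone is used.
    """
    set_p, set_q = set(markers_p.features), set(markers_q.features)
    union = sorted(set_p | set_q)
    if not union:
        raise ValueError("both clusters have empty marker sets")
    if not set_p or not set_q:
        warnings.warn(
            "a cluster has no markers; using cosine similarity alone", stacklevel=2
        )
        overlap = np.nan
    else:
        overlap = len(set_p & set_q) / min(len(set_p), len(set_q))
    mu_p = _mean_profile(fm_p, labels_p, confident_p, markers_p.cluster_id, union)
    mu_q = _mean_profile(fm_q, labels_q, confident_q, markers_q.cluster_id, union)
    norm = np.linalg.norm(mu_p) * np.linalg.norm(mu_q)
    cosine = 0.0 if norm == 0 else float(np.clip(mu_p @ mu_q / norm, 0.0, 1.0))
    similarity = cosine if np.isnan(overlap) else (overlap + cosine) / 2.0
    return (overlap, cosine, float(similarity))


def shared_pairs(
    datasets: dict,
    threshold: float = 0.6,
) -> SharedPairSet:
    """Infer shared clusters from all cross-dataset cluster pairs.

    ``datasets`` maps dataset id -> dict with keys ``fm`` (FeatureMatrix),
    ``labels``, ``confident`` and ``markers`` (dict cluster_id ->
    MarkerSet).  Every cluster pair across every dataset pair is scored;
    pairs with similarity strictly greater than ``threshold`` are shared.
    One cluster may match several others.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    rows = []
    ids = list(datasets)
    for di, dj in itertools.combinations(ids, 2):
        a, b = datasets[di], datasets[dj]
        for cp, mp in a["markers"].items():
            for cq, mq in b["markers"].items():
                if len(mp) == 0 and len(mq) == 0:
                    overlap, cosine, sim = (np.nan, 0.0, 0.0)
                else:
                    overlap, cosine, sim = cluster_similarity(
                        mp, mq,
                        a["fm"], b["fm"],
                        a["labels"], b["labels"],
                        a["confident"], b["confident"],
                    )
                rows.append((di, cp, dj, cq, overlap, cosine, sim))
    edges = pd.DataFrame(
        rows,
        columns=[
            "dataset_i", "cluster_p", "dataset_j", "cluster_q",
            "overlap", "cosine", "similarity",
        ],
    )
    edges["passed"] = edges["similarity"] > threshold
    return SharedPairSet(edges=edges, threshold=threshold)
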