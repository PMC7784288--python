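"""Evaluation metrics for integration quality.

Covers clustering agreement with ground truth (NMI, ARI, Jaccard,
Purity), geometric cell-type separation (silhouette), batch/cell-type
mixing through the local inverse Simpson's index (LISI) and its F1
combination, preservation of condition-specific populations (specificity
score), pseudotime concordance (POS, Kendall tau), principal-curve
pseudotime conservation, and the rank-based overall score used to
compare integration methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import kendalltau, pearsonr
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "LabeledEmbedding",
    "MetricReport",
    "clustering_agreement",
    "silhouette",
    "lisi",
    "lisi_f1",
    "specificity",
    "pos",
    "principal_curve_pseudotime",
    "pseudotime_conservation",
    "overall_score",
]


@dataclass
class LabeledEmbedding:
    """Embedding coordinates together with batch/type labels for evaluation."""

    coordinates: np.ndarray
    batch_labels: np.ndarray | None = None
    type_labels: np.ndarray | None = None
    specific_mask: np.ndarray | None = None
    pseudotime: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be cells x dimensions")
        n = self.coordinates.shape[0]
        for name in ("batch_labels", "type_labels", "specific_mask", "pseudotime"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)


@dataclass
class MetricReport:
    """Named scalar metrics plus optional per-category overall scores."""

    scores: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.scores.items()), columns=["metric", "value"]
        )


# ---------------------------------------------------------------- agreement


def _contingency(truth, pred) -> np.ndarray:
    t_codes, _ = pd.factorize(np.asarray(truth))
    p_codes, _ = pd.factorize(np.asarray(pred))
    table = np.zeros((t_codes.max() + 1, p_codes.max() + 1), dtype=np.int64)
    np.add.at(table, (t_codes, p_codes), 1)
    return table


def clustering_agreement(truth, pred) -> dict:
    """NMI, ARI, Jaccard and Purity between two labelings.

    NMI is normalized by the arithmetic mean of the entropies; ARI uses
    the permutation-model adjustment; Jaccard counts cell pairs
    co-assigned in both labelings against pairs co-assigned in either;
    Purity is the fraction of cells in the majority truth class of their
    predicted cluster.  All lie in [0, 1].
    """
    truth, pred = np.asarray(truth), np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("label vectors differ in length")
    table = _contingency(truth, pred)
    n = table.sum()
    if table.shape == (1, 1):
        # degenerate single-label case: identical partitions
        return {"nmi": 1.0, "ari": 1.0, "jaccard": 1.0, "purity": 1.0}
    nmi = float(normalized_mutual_info_score(truth, pred, average_method="arithmetic"))
    ari = float(adjusted_rand_score(truth, pred))
    comb = lambda x: x * (x - 1) // 2
    both = comb(table).sum()  # pairs together in truth and pred
    in_truth = comb(table.sum(axis=1)).sum()
    in_pred = comb(table.sum(axis=0)).sum()
    union = in_truth + in_pred - both
    jaccard = float(both / union) if union else 1.0
    purity = float(table.max(axis=0).sum() / n)
    return {"nmi": nmi, "ari": ari, "jaccard": jaccard, "purity": purity}


# ---------------------------------------------------------------- silhouette


def silhouette(coordinates, labels) -> float:
    """Mean silhouette width s(i) = (b(i) - a(i)) / max(a(i), b(i)).

    a(i) is the mean Euclidean distance of cell i to the other cells of
    its cluster; b(i) the smallest, over the other clusters, of the mean
    distance to that cluster's cells.  Singleton clusters score 0.
    """
    x = np.asarray(coordinates, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    d = cdist(x, x)
    n = x.shape[0]
    s = np.zeros(n)
    masks = {lab: labels == lab for lab in uniq}
    sizes = {lab: masks[lab].sum() for lab in uniq}
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            s[i] = 0.0
            continue
        a = d[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(d[i, masks[lab]].mean() for lab in uniq if lab != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


# ---------------------------------------------------------------------- LISI


def lisi(
    coordinates,
    labels,
    perplexity: float = 30.0,
    return_raw: bool = False,
):
    """Local inverse Simpson's index of label diversity, normalized.

    Per cell, a Gaussian kernel over its 3*perplexity nearest neighbors
    is calibrated (binary search on the bandwidth) so the neighbor-weight
    entropy equals log(perplexity); the inverse Simpson's index of the
    label probabilities under those weights gives the per-cell score,
    which ranges from 1 (single label locally) to the number of labels
    (uniform mixing).  The returned scalar is the paper-style
    normalization (median - min) / (max - min) over cells; with
    ``return_raw`` the per-cell raw scores are returned as well.
    """
    x = np.asarray(coordinates, dtype=float)
    codes, uniq = pd.factorize(np.asarray(labels))
    n, n_labels = x.shape[0], uniq.size
    if n_labels < 2:
        raise ValueError("need at least two distinct labels")
    k = min(n - 1, int(np.ceil(3 * perplexity)))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    target = np.log(perplexity)
    raw = np.empty(n)
    d2 = dist**2
    for i in range(n):
        beta = _calibrate_beta(d2[i], target)
        w = np.exp(-beta * d2[i])
        total = w.sum()
        if total <= 0:
            raw[i] = 1.0
            continue
        p = w / total
        label_p = np.bincount(codes[idx[i]], weights=p, minlength=n_labels)
        raw[i] = 1.0 / np.sum(label_p**2)
    spread = raw.max() - raw.min()
    if spread == 0:
        warnings.warn("degenerate LISI spread (max == min); returning 0", stacklevel=2)
        scalar = 0.0
    else:
        scalar = float((np.median(raw) - raw.min()) / spread)
    return (scalar, raw) if return_raw else scalar


def _calibrate_beta(
    d2: np.ndarray, target_entropy: float, tol: float = 1e-5, max_iter: int = 50
) -> float:
    """Binary search for the Gaussian precision hitting the target entropy."""
    beta, lo, hi = 1.0, 0.0, np.inf
    scale = d2.mean() or 1.0
    beta = 1.0 / scale
    for _ in range(max_iter):
        w = np.exp(-beta * d2)
        total = w.sum()
        if total <= 0:
            entropy = 0.0
        else:
            p = w / total
            nzp = p[p > 0]
            entropy = float(-np.sum(nzp * np.log(nzp)))
        if abs(entropy - target_entropy) < tol:
            break
        if entropy > target_entropy:
            lo = beta
            beta = beta * 2 if np.isinf(hi) else (beta + hi) / 2
        else:
            hi = beta
            beta = (lo + beta) / 2
    return beta


def lisi_f1(blisi_norm: float, clisi_norm: float) -> float:
    """F1-style combination of batch mixing and cell-type separation.

    F1 = 2 * bLISI * (1 - cLISI) / (1 - cLISI + bLISI); bLISI rewards
    batch mixing, (1 - cLISI) rewards cell-type separation.
    """
    for name, v in (("bLISI", blisi_norm), ("cLISI", clisi_norm)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    denom = 1 - clisi_norm + blisi_norm
    if denom == 0:
        return 0.0
    return float(2 * blisi_norm * (1 - clisi_norm) / denom)


# --------------------------------------------------------------- specificity


def specificity(coordinates, specific_mask, k: int = 20) -> float:
    """Preservation of condition-specific populations.

    For each condition-specific cell, the fraction of its k nearest
    neighbors that are non-specific cells; the score is one minus the
    median of those fractions.  1 means specific cells sit in their own
    neighborhood, 0 means they are fully absorbed by other cells.
    """
    x = np.asarray(coordinates, dtype=float)
    mask = np.asarray(specific_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no condition-specific cells flagged")
    if x.shape[0] < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x[mask])
    neigh = np.empty((mask.sum(), k), dtype=int)
    rows = np.flatnonzero(mask)
    for r, (cell, nb) in enumerate(zip(rows, idx)):
        nb = nb[nb != cell][:k]
        neigh[r] = nb
    ratios = (~mask[neigh]).sum(axis=1) / k
    return float(1.0 - np.median(ratios))


# ---------------------------------------------------------------- pseudotime


def pos(pseudotime, gold) -> tuple[float, float]:
    """Pseudotime ordering score and Kendall tau against a gold standard.

    POS = C / (C + N_C) over all cell pairs, where C counts pairs ordered
    the same way in both vectors and N_C pairs ordered oppositely; tied
    pairs (in either vector) count as neither.  Kendall tau is the
    tie-corrected tau-b.
    """
    p = np.asarray(pseudotime, dtype=float)
    g = np.asarray(gold, dtype=float)
    if p.shape != g.shape or p.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    if np.unique(p).size == 1 or np.unique(g).size == 1:
        raise ValueError("all values tied in one of the vectors")
    dp = np.sign(p[:, None] - p[None, :])
    dg = np.sign(g[:, None] - g[None, :])
    prod = np.triu(dp * dg, k=1)
    c = int((prod > 0).sum())
    nc = int((prod < 0).sum())
    if c + nc == 0:
        raise ValueError("no untied pairs to compare")
    tau = float(kendalltau(p, g).statistic)
    return float(c / (c + nc)), tau


def principal_curve_pseudotime(
    coordinates,
    span: float = 0.3,
    max_iter: int = 20,
    tol: float = 1e-4,
    n_nodes: int = 100,
) -> np.ndarray:
    """Pseudotime as arc-length position along a fitted principal curve.

    The curve starts from the first principal component and is refined by
    iterated projection-smoothing: cells are ordered by their current
    arc-length parameter, each coordinate is smoothed by a running mean
    over a window of ``span`` times the cell count, the smoothed cloud is
    condensed to ``n_nodes`` polyline nodes, and cells are orthogonally
    re-projected onto the polyline.  Iteration stops when the mean
    projection displacement falls below ``tol`` of the curve length.
    """
    x = np.asarray(coordinates, dtype=float)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    t = u[:, 0] * s[0]
    prev_proj = None
    for _ in range(max_iter):
        order = np.argsort(t, kind="stable")
        window = max(3, int(np.ceil(span * n)))
        smoothed = _running_mean(x[order], window)
        nodes = _condense(smoothed, n_nodes)
        t_new, proj, length = _project_polyline(x, nodes)
        if prev_proj is not None and length > 0:
            shift = np.linalg.norm(proj - prev_proj, axis=1).mean()
            if shift < tol * length:
                t = t_new
                break
        prev_proj = proj
        t = t_new
    else:
        warnings.warn(
            "principal curve did not converge; returning last iterate", stacklevel=2
        )
    return t


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    n = x.shape[0]
    half = window // 2
    cums = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cums[hi] - cums[lo]) / (hi - lo)[:, None]


def _condense(points: np.ndarray, n_nodes: int) -> np.ndarray:
    n = points.shape[0]
    if n <= n_nodes:
        return points
    groups = np.array_split(np.arange(n), n_nodes)
    return np.vstack([points[g].mean(axis=0) for g in groups])


def _project_polyline(x: np.ndarray, nodes: np.ndarray):
    """Orthogonal projection of points onto a polyline; arc-length positions."""
    seg_vec = np.diff(nodes, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    keep = seg_len > 0
    if not keep.any():
        return np.zeros(x.shape[0]), np.tile(nodes[0], (x.shape[0], 1)), 0.0
    starts, vecs, lens = nodes[:-1][keep], seg_vec[keep], seg_len[keep]
    cumlen = np.concatenate([[0.0], np.cumsum(lens)])
    best_d2 = np.full(x.shape[0], np.inf)
    best_t = np.zeros(x.shape[0])
    best_p = np.zeros_like(x)
    for s_i in range(starts.shape[0]):
        rel = x - starts[s_i]
        frac = np.clip(rel @ vecs[s_i] / lens[s_i] ** 2, 0.0, 1.0)
        proj = starts[s_i] + frac[:, None] * vecs[s_i]
        d2 = np.sum((x - proj) ** 2, axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_t[better] = cumlen[s_i] + frac[better] * lens[s_i]
        best_p[better] = proj[better]
    return best_t, best_p, float(cumlen[-1])


def pseudotime_conservation(
    embeddings_before: dict,
    embedding_after,
    batch_labels,
    **curve_kwargs,
) -> dict:
    """Per-batch Pearson correlation of principal-curve pseudotime.

    ``embeddings_before`` maps batch id -> coordinates of that batch's
    cells before integration; ``embedding_after`` holds the integrated
    coordinates of all cells, with ``batch_labels`` assigning rows to
    batches.  A principal curve is fit separately to each pre-integration
    embedding and to the integrated embedding; the statistic per batch is
    |Pearson r| between the two pseudotimes (curve orientation is
    arbitrary, so only magnitude is meaningful).
    """
    after = np.asarray(embedding_after, dtype=float)
    batch_labels = np.asarray(batch_labels)
    t_after = principal_curve_pseudotime(after, **curve_kwargs)
    out = {}
    for batch, coords in embeddings_before.items():
        mask = batch_labels == batch
        if mask.sum() != np.asarray(coords).shape[0]:
            raise ValueError(f"batch {batch!r}: cell count mismatch")
        t_before = principal_curve_pseudotime(np.asarray(coords), **curve_kwargs)
        r = pearsonr(t_before, t_after[mask]).statistic
        out[batch] = float(abs(r))
    return out


# ------------------------------------------------------------- overall score


def overall_score(metric_table: pd.DataFrame, category_map: dict) -> pd.DataFrame:
    """Rank-average overall scores across methods.

    ``metric_table`` is methods x metrics (larger is better everywhere).
    Per metric the M methods are ranked descending and awarded M..1
    points (ties share the mean of their point range); the overall score
    of a category is the mean of its metrics' points; an 'overall'
    column averages across all metrics.  ``category_map`` maps category
    name -> list of metric columns.
    """
    if metric_table.shape[0] < 2:
        raise ValueError("need at least two methods to rank")
    m_methods = metric_table.shape[0]
    usable = []
    points = {}
    for col in metric_table.columns:
        vals = metric_table[col]
        if vals.isna().any():
            warnings.warn(f"metric {col!r} has missing values; skipped", stacklevel=2)
            continue
        # rank 1 = best; points = M + 1 - rank, ties averaged
        points[col] = m_methods + 1 - vals.rank(ascending=False, method="average")
        usable.append(col)
    pts = pd.DataFrame(points, index=metric_table.index)
    out = {}
    for cat, cols in category_map.items():
        cols = [c for c in cols if c in usable]
        if cols:
            out[cat] = pts[cols].mean(axis=1)
    out["overall"] = pts[usable].mean(axis=1)
    return pd.DataFrame(out)
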