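"""Variance-subtraction correction: confounding matrix, eigenproblem, projection.

Differences between matched (shared) clusters across datasets are pure
technical variation.  A signed index matrix Y pairs confident cells of
each shared cluster pair so that Yᵀ X̂ stacks the paired difference
vectors; the correction vectors V then maximize

    Vᵀ X̂ᵀ X̂ V  -  λ Vᵀ X̂ᵀ Y Yᵀ X̂ V,    ‖V_,i‖₂ ≤ 1,

i.e. total variance minus λ times technical variance, solved as the
eigenvectors of the symmetric matrix A = X̂ᵀX̂ - λ X̂ᵀYYᵀX̂ with strictly
positive eigenvalues.  Projecting any cells onto V (L = XV) yields the
shared embedding; the basis can be reused to place new datasets into the
same coordinate frame.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .preprocess import FeatureMatrix

__all__ = [
    "ConfoundingMatrix",
    "CorrectionBasis",
    "Embedding",
    "build_confounding",
    "learn_correction",
    "technical_ratio",
    "project",
    "project_new",
]


@dataclass
class ConfoundingMatrix:
    """Signed pairing matrix Y (confident cells x l).

    Each shared cluster pair contributes a disjoint block of n_pq =
    min(n_p, n_q) columns; every column has exactly one +1 (a cell of the
    first cluster) and one -1 (its matched cell in the second), so rows of
    YᵀX̂ are the paired difference vectors.
    """

    Y: sp.csr_matrix
    block_index: dict  # pair key -> (start, stop) column range
    pairing: list  # per column, (row_plus, row_minus)

    @property
    def n_columns(self) -> int:
        return self.Y.shape[1]


@dataclass
class CorrectionBasis:
    """Correction vectors with their eigenvalues and fit metadata."""

    V: np.ndarray  # m x k, orthonormal columns, descending eigenvalues
    eigenvalues: np.ndarray  # strictly positive, descending
    lam: float
    k_requested: int
    feature_ids: list
    center: np.ndarray  # column means of X̂ subtracted before the eigenproblem
    R: float = np.nan  # technical-variation ratio

    @property
    def k(self) -> int:
        return self.V.shape[1]

    def save(self, path) -> None:
        np.savez(
            path,
            V=self.V,
            eigenvalues=self.eigenvalues,
            lam=self.lam,
            k_requested=self.k_requested,
            feature_ids=np.asarray(self.feature_ids, dtype=object),
            center=self.center,
            R=self.R,
        )

    @classmethod
    def load(cls, path) -> "CorrectionBasis":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                V=z["V"],
                eigenvalues=z["eigenvalues"],
                lam=float(z["lam"]),
                k_requested=int(z["k_requested"]),
                feature_ids=[str(f) for f in z["feature_ids"]],
                center=z["center"],
                R=float(z["R"]),
            )


@dataclass
class Embedding:
    """Shared low-dimensional coordinates L = XV for all cells."""

    L: np.ndarray
    cell_ids: list
    batch_ids: list

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.L, columns=[f"L{i + 1}" for i in range(self.L.shape[1])]
        )
        df.insert(0, "batch", self.batch_ids)
        df.insert(0, "cell_id", self.cell_ids)
        return df


def _pair_seed(master_seed: int, key_a, key_b) -> int:
    """Seed derived from the unordered pair identity; order-invariant."""
    token = json.dumps(sorted([list(map(str, key_a)), list(map(str, key_b))]))
    return (zlib.crc32(token.encode()) + int(master_seed)) % (2**31)


def build_confounding(
    x_hat: FeatureMatrix,
    pairs,
    cluster_keys: list,
    seed: int = 0,
) -> ConfoundingMatrix:
    """Assemble Y from the shared cluster pairs over the confident-cell stack.

    ``x_hat`` stacks the confident cells of all datasets; ``cluster_keys``
    gives, per row, the (dataset, cluster) identity.  For each shared pair
    the larger side is downsampled uniformly without replacement to n_pq =
    min(n_p, n_q) cells; both sides are shuffled with a seed derived from
    the unordered pair identity, making Y invariant to dataset input
    order.  Column blocks of different pairs are disjoint.
    """
    pair_rows = pairs.pairs if hasattr(pairs, "pairs") else pairs
    if len(pair_rows) == 0:
        raise ValueError("no shared cluster pairs")
    index_of: dict = {}
    for i, key in enumerate(cluster_keys):
        index_of.setdefault((str(key[0]), key[1]), []).append(i)

    rows_plus, rows_minus = [], []
    block_index, pairing = {}, []
    start = 0
    for _, row in pair_rows.iterrows():
        key_p = (str(row["dataset_i"]), row["cluster_p"])
        key_q = (str(row["dataset_j"]), row["cluster_q"])
        idx_p = index_of.get(key_p, [])
        idx_q = index_of.get(key_q, [])
        if not idx_p or not idx_q:
            warnings.warn(
                f"pair {key_p} ~ {key_q} has a side with no confident cells; skipped",
                stacklevel=2,
            )
            continue
        # canonical orientation: lexicographically smaller key gets the +1 side
        if [list(map(str, key_q))] < [list(map(str, key_p))]:
            key_p, key_q = key_q, key_p
            idx_p, idx_q = idx_q, idx_p
        n_pq = min(len(idx_p), len(idx_q))
        rng = np.random.default_rng(_pair_seed(seed, key_p, key_q))
        sel_p = rng.permutation(idx_p)[:n_pq]
        sel_q = rng.permutation(idx_q)[:n_pq]
        rows_plus.extend(sel_p.tolist())
        rows_minus.extend(sel_q.tolist())
        pairing.extend(zip(sel_p.tolist(), sel_q.tolist()))
        block_index[(key_p, key_q)] = (start, start + n_pq)
        start += n_pq
    if start == 0:
        raise ValueError("every shared pair was empty on one side")
    n = x_hat.n_cells
    cols = np.arange(start)
    data = np.concatenate([np.ones(start), -np.ones(start)])
    rows = np.concatenate([rows_plus, rows_minus])
    y = sp.csr_matrix(
        (data, (rows, np.concatenate([cols, cols]))), shape=(n, start)
    )
    return ConfoundingMatrix(Y=y, block_index=block_index, pairing=pairing)


def learn_correction(
    x_hat: FeatureMatrix,
    confounding: ConfoundingMatrix | None,
    lam: float = 10.0,
    k: int = 40,
    center: bool = True,
) -> CorrectionBasis:
    """Solve the penalized eigenproblem for the correction vectors.

    Forms A = X̂ᵀX̂ - λ X̂ᵀYYᵀX̂ on the (optionally column-centered)
    confident-cell stack and keeps the eigenvectors of the strictly
    positive eigenvalues, at most ``k``, in descending order.  Centering
    does not alter the technical term because Yᵀ1 = 0 by construction.
    With λ = 0 or no confounding matrix this reduces to PCA of X̂.
    """
    x = np.asarray(x_hat.values, dtype=float)
    m = x.shape[1]
    if m < 2:
        raise ValueError("need at least 2 features")
    mu = x.mean(axis=0) if center else np.zeros(m)
    xc = x - mu
    if confounding is None or lam == 0:
        # PCA limit: a thin SVD of X̂ is better conditioned than X̂ᵀX̂
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        evals, evecs = s**2, vt.T
    else:
        ytx = confounding.Y.T @ xc
        a = xc.T @ xc - lam * (ytx.T @ ytx)
        a = (a + a.T) / 2.0
        evals, evecs = np.linalg.eigh(a)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-12 * abs(evals[0])) if evals.size else 0.0
    positive = evals > tol
    if not positive.any():
        raise ValueError("technical variation dominates; lower lambda")
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} strictly positive eigenvalues; returning {n_pos} "
            f"correction vectors instead of {k}",
            stacklevel=2,
        )
    keep = min(k, n_pos)
    v = evecs[:, :keep]
    # deterministic sign: the largest-magnitude entry of each column is positive
    flip = v[np.argmax(np.abs(v), axis=0), np.arange(keep)] < 0
    v[:, flip] *= -1
    basis = CorrectionBasis(
        V=v,
        eigenvalues=evals[:keep],
        lam=float(lam),
        k_requested=int(k),
        feature_ids=list(x_hat.feature_ids),
        center=mu,
    )
    if confounding is not None:
        basis.R = technical_ratio(x_hat, confounding, basis)
    else:
        basis.R = 0.0
    return basis


def technical_ratio(
    x_hat: FeatureMatrix, confounding: ConfoundingMatrix | None, basis: CorrectionBasis
) -> float:
    """Share of technical variation in the projected data.

    R = tr(VᵀX̂ᵀYYᵀX̂V) / [tr(VᵀX̂ᵀYYᵀX̂V) + tr(VᵀX̂ᵀX̂V)] ∈ [0, 1].
    """
    xc = np.asarray(x_hat.values, dtype=float) - basis.center
    xv = xc @ basis.V
    total = float(np.sum(xv**2))
    if total == 0:
        raise ValueError("projected data X̂V is identically zero")
    if confounding is None:
        return 0.0
    yxv = confounding.Y.T @ xv
    tech = float(np.sum(np.asarray(yxv) ** 2))
    return tech / (tech + total)


def project(x_all: FeatureMatrix, basis: CorrectionBasis) -> Embedding:
    """Project cells onto the correction vectors: L = (X - center) V."""
    if list(x_all.feature_ids) != list(basis.feature_ids):
        missing = set(basis.feature_ids) - set(x_all.feature_ids)
        raise ValueError(
            f"feature mismatch with the correction basis; missing: {sorted(missing)[:10]}"
        )
    l = (np.asarray(x_all.values, dtype=float) - basis.center) @ basis.V
    return Embedding(L=l, cell_ids=list(x_all.cell_ids), batch_ids=list(x_all.batch_ids))


def project_new(x_new: FeatureMatrix, basis: CorrectionBasis) -> Embedding:
    """Project a new (unseen) dataset into the existing shared embedding.

    Features are matched by id to the basis feature space; features the
    new dataset lacks are zero-filled (at most 50% may be missing).  The
    stored centering vector is applied, so the coordinates are directly
    comparable with the training embedding.
    """
    col = {f: j for j, f in enumerate(x_new.feature_ids)}
    missing = [f for f in basis.feature_ids if f not in col]
    if len(missing) > 0.5 * len(basis.feature_ids):
        raise ValueError(
            f"{len(missing)}/{len(basis.feature_ids)} basis features missing "
            "from the new dataset"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} basis features absent from the new dataset; zero-filled",
            stacklevel=2,
        )
    x = np.zeros((x_new.n_cells, len(basis.feature_ids)))
    for j, f in enumerate(basis.feature_ids):
        if f in col:
            x[:, j] = np.asarray(x_new.values)[:, col[f]]
    l = (x - basis.center) @ basis.V
    return Embedding(L=l, cell_ids=list(x_new.cell_ids), batch_ids=list(x_new.batch_ids))
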