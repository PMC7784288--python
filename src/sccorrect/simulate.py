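"""Synthetic multi-batch single-cell count data with full ground truth.

A gamma-Poisson (negative-binomial-like) generator in the spirit of
Splatter: gene base means are gamma-distributed, discrete subpopulations
multiply their differentially expressed (DE) genes by a fold change,
batches multiply all genes by per-gene lognormal factors, cells carry a
lognormal library-size factor, and observed counts are Poisson.  A
trajectory variant interpolates gene programs log-linearly along a
latent time.  Six presets mirror common benchmark designs: identical
compositions, imbalanced compositions, three batches, a continuous
trajectory, a larger many-batch design, and nested sub-batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .preprocess import ExpressionDataset

__all__ = [
    "BatchSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_trajectory",
    "preset",
    "PRESET_NAMES",
]


@dataclass
class BatchSpec:
    """One batch: its size, group composition and (optional) parent set."""

    name: str
    n_cells: int
    group_proportions: list[float]
    parent_set: str | None = None  # for nested sub-batch designs

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        props = np.asarray(self.group_proportions, dtype=float)
        if props.min() < 0 or not np.isclose(props.sum(), 1.0):
            raise ValueError("group proportions must be nonnegative and sum to 1")


@dataclass
class SimConfig:
    """Parameters of one simulation scenario.  ``seed`` is mandatory."""

    n_genes: int
    batches: list[BatchSpec]
    n_groups: int
    seed: int
    de_frac: float = 0.08
    fold_change: float = 3.0
    batch_factor_loc: float = 0.0
    batch_factor_scale: float = 0.25
    set_factor_scale: float = 0.0  # extra factor shared by sub-batches of a set
    library_sigma: float = 0.2
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    trajectory: bool = False

    def __post_init__(self):
        if self.n_genes <= 0 or not self.batches:
            raise ValueError("config needs positive n_genes and at least one batch")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        for b in self.batches:
            if len(b.group_proportions) != self.n_groups:
                raise ValueError(
                    f"batch {b.name}: expected {self.n_groups} group proportions"
                )


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the counts."""

    group_labels: dict  # batch name -> array of group ids per cell
    de_genes: dict  # group id -> list of gene ids upregulated in that group
    batch_factors: dict  # batch name -> per-gene multiplicative factor
    pseudotime: dict = field(default_factory=dict)  # batch name -> latent time

    def stacked_groups(self, batch_order) -> np.ndarray:
        return np.concatenate([self.group_labels[b] for b in batch_order])


def _group_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n cells to groups."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _batch_factor(cfg: SimConfig, rng: np.random.Generator, set_factors: dict, b: BatchSpec):
    factor = rng.lognormal(cfg.batch_factor_loc, cfg.batch_factor_scale, cfg.n_genes)
    if b.parent_set is not None and cfg.set_factor_scale > 0:
        if b.parent_set not in set_factors:
            set_factors[b.parent_set] = rng.lognormal(
                cfg.batch_factor_loc, cfg.set_factor_scale, cfg.n_genes
            )
        factor = factor * set_factors[b.parent_set]
    return factor


def simulate_counts(cfg: SimConfig) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Draw one multi-batch dataset with discrete subpopulations.

    Deterministic given ``cfg.seed``; the same seed reproduces the counts
    bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"gene_{j:05d}" for j in range(cfg.n_genes)]
    base = rng.gamma(shape=cfg.mean_shape, scale=1.0 / cfg.mean_rate, size=cfg.n_genes)
    base = np.maximum(base, 1e-4)
    n_de = max(1, round(cfg.de_frac * cfg.n_genes))
    group_factor = np.ones((cfg.n_groups, cfg.n_genes))
    de_genes = {}
    for g in range(cfg.n_groups):
        de = rng.choice(cfg.n_genes, size=n_de, replace=False)
        group_factor[g, de] = cfg.fold_change
        de_genes[g] = [gene_ids[j] for j in sorted(de)]

    datasets, group_labels, batch_factors = [], {}, {}
    set_factors: dict = {}
    for b in cfg.batches:
        bf = _batch_factor(cfg, rng, set_factors, b)
        counts_per_group = _group_counts(
            np.asarray(b.group_proportions, dtype=float), b.n_cells
        )
        labels = np.repeat(np.arange(cfg.n_groups), counts_per_group)
        lib = rng.lognormal(0.0, cfg.library_sigma, b.n_cells)
        mean = base[None, :] * group_factor[labels] * bf[None, :] * lib[:, None]
        counts = rng.poisson(mean)
        datasets.append(
            ExpressionDataset(
                values=sp.csr_matrix(counts),
                cell_ids=[f"{b.name}_cell_{i:05d}" for i in range(b.n_cells)],
                feature_ids=list(gene_ids),
                batch_id=b.name,
            )
        )
        group_labels[b.name] = labels
        batch_factors[b.name] = bf
    truth = GroundTruth(
        group_labels=group_labels, de_genes=de_genes, batch_factors=batch_factors
    )
    return datasets, truth


def simulate_trajectory(cfg: SimConfig) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Draw a continuous-trajectory dataset across batches.

    Each cell has a latent time t ~ Uniform(0, 1); gene means interpolate
    log-linearly between a start program (the base means) and an end
    program (base means with the DE genes scaled by the fold change).
    Batch and library factors apply as in the discrete generator; t is
    recorded as gold-standard pseudotime.
    """
    if not cfg.trajectory:
        raise ValueError("config does not enable a trajectory block")
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"gene_{j:05d}" for j in range(cfg.n_genes)]
    base = rng.gamma(shape=cfg.mean_shape, scale=1.0 / cfg.mean_rate, size=cfg.n_genes)
    base = np.maximum(base, 1e-4)
    n_de = max(1, round(cfg.de_frac * cfg.n_genes))
    de = rng.choice(cfg.n_genes, size=n_de, replace=False)
    log_ratio = np.zeros(cfg.n_genes)
    log_ratio[de] = np.log(cfg.fold_change)

    datasets, pseudotime, batch_factors = [], {}, {}
    set_factors: dict = {}
    for b in cfg.batches:
        bf = _batch_factor(cfg, rng, set_factors, b)
        t = rng.uniform(0.0, 1.0, b.n_cells)
        lib = rng.lognormal(0.0, cfg.library_sigma, b.n_cells)
        mean = base[None, :] * np.exp(t[:, None] * log_ratio[None, :])
        mean = mean * bf[None, :] * lib[:, None]
        counts = rng.poisson(mean)
        datasets.append(
            ExpressionDataset(
                values=sp.csr_matrix(counts),
                cell_ids=[f"{b.name}_cell_{i:05d}" for i in range(b.n_cells)],
                feature_ids=list(gene_ids),
                batch_id=b.name,
            )
        )
        pseudotime[b.name] = t
        batch_factors[b.name] = bf
    truth = GroundTruth(
        group_labels={b.name: np.zeros(b.n_cells, dtype=int) for b in cfg.batches},
        de_genes={0: [gene_ids[j] for j in sorted(de)]},
        batch_factors=batch_factors,
        pseudotime=pseudotime,
    )
    return datasets, truth


PRESET_NAMES = ("s1", "s2", "s3", "s4", "s5", "s6")


def preset(name: str, seed: int = 0) -> SimConfig:
    """Reduced-scale configurations for the six benchmark scenarios.

    s1 — two batches, identical compositions (5 groups);
    s2 — imbalanced: batch 1 has 6 groups, batch 2 only the first 4;
    s3 — three batches sharing 4 groups (projection/hold-out scenario);
    s4 — two batches along a continuous trajectory;
    s5 — larger design: four batches, 8 groups;
    s6 — 16 nested sub-batches (4 sets x 4 sub-batches, 5 groups).
    """
    eq = lambda g: [1.0 / g] * g
    if name == "s1":
        return SimConfig(
            n_genes=1500,
            batches=[BatchSpec("b1", 600, eq(5)), BatchSpec("b2", 600, eq(5))],
            n_groups=5,
            seed=seed,
        )
    if name == "s2":
        shared4 = [0.25, 0.25, 0.25, 0.25, 0.0, 0.0]
        return SimConfig(
            n_genes=1500,
            batches=[
                BatchSpec("b1", 900, eq(6)),
                BatchSpec("b2", 600, shared4),
            ],
            n_groups=6,
            seed=seed,
        )
    if name == "s3":
        return SimConfig(
            n_genes=1500,
            batches=[
                BatchSpec("b1", 500, eq(4)),
                BatchSpec("b2", 500, eq(4)),
                BatchSpec("b3", 500, eq(4)),
            ],
            n_groups=4,
            seed=seed,
        )
    if name == "s4":
        return SimConfig(
            n_genes=1500,
            batches=[BatchSpec("b1", 500, [1.0]), BatchSpec("b2", 500, [1.0])],
            n_groups=1,
            seed=seed,
            de_frac=0.3,
            fold_change=4.0,
            trajectory=True,
        )
    if name == "s5":
        return SimConfig(
            n_genes=1500,
            batches=[BatchSpec(f"b{i + 1}", 1200, eq(8)) for i in range(4)],
            n_groups=8,
            seed=seed,
        )
    if name == "s6":
        batches = [
            BatchSpec(f"set{s + 1}_sub{b + 1}", 150, eq(5), parent_set=f"set{s + 1}")
            for s in range(4)
            for b in range(4)
        ]
        return SimConfig(
            n_genes=1500,
            batches=batches,
            n_groups=5,
            seed=seed,
            batch_factor_scale=0.1,
            set_factor_scale=0.25,
        )
    raise ValueError(f"unknown preset {name!r}; choose one of {PRESET_NAMES}")
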