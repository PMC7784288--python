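# sccorrect

Batch-effect correction for single-cell transcriptomic and epigenomic data
via shared-cluster variance subtraction.

## The problem

When several single-cell datasets — different replicates, conditions,
time points, or platforms — are analyzed jointly, systematic technical
differences (batch effects) mix with genuine biological differences.
Most integration methods force all datasets onto a common manifold,
which can *over-align*: condition-specific cell populations get merged
into populations they do not belong to, erasing exactly the biology the
experiment was designed to find. This package removes technical
variation while explicitly preserving dataset-specific populations,
which matters most when cell-type compositions are imbalanced across
conditions.

## The method

Each dataset is clustered **separately** (consensus Leiden over
resolutions 0.1–0.5 on a shared-nearest-neighbor graph, with the cluster
number set by the consensus-matrix spectrum). Within each cluster, the
cells most similar to their peers (average SNN similarity above the
cluster's third quartile Q₃) are the *confident cells*. Clusters are
matched **across** datasets by the average of a marker-overlap score
(two-part hurdle likelihood-ratio test; p < 0.05, ln-fold-change > 0.25,
expressed fraction > 25%) and the cosine similarity of their mean
profiles; pairs above a threshold *T* (default 0.6) are *shared
clusters*.

Differences between matched clusters are, by construction, technical.
A signed pairing matrix *Y* couples confident cells of each shared pair
so that *Yᵀ X̂* stacks paired difference vectors, and the correction
vectors *V* solve

```
max_V  Vᵀ X̂ᵀ X̂ V − λ Vᵀ X̂ᵀ Y Yᵀ X̂ V ,   ‖V·ᵢ‖₂² ≤ 1 ,
```

i.e. the eigenvectors with strictly positive eigenvalues of
*X̂ᵀX̂ − λ X̂ᵀYYᵀX̂* (λ = 10 by default; λ = 0 reduces to PCA). The shared
embedding of **all** cells is *L = XV*; dataset-specific clusters are
carried along by the same projection, and new datasets can be placed
into the same coordinate frame later with the stored basis. The share of
technical variation removed is reported as

```
R = tr(VᵀX̂ᵀYYᵀX̂V) / [tr(VᵀX̂ᵀYYᵀX̂V) + tr(VᵀX̂ᵀX̂V)] .
```

The package also ships the evaluation metrics used to score
integrations (NMI/ARI/Jaccard/Purity, silhouette, LISI-derived F1,
specificity score, POS/Kendall, principal-curve pseudotime conservation,
rank-based overall scores) and a gamma-Poisson multi-batch simulator
with six benchmark scenarios (`preset("s1")` … `preset("s6")`) so the
entire pipeline is testable without downloading data.

## Worked example

Integrate the imbalanced scenario: batch 1 carries six cell
populations, batch 2 only four of them.

```python
import numpy as np
from sccorrect.simulate import preset, simulate_counts
from sccorrect.pipeline import run_integration, RunConfig
from sccorrect.metrics import silhouette, specificity

cfg = preset("s2", seed=1)                      # imbalanced: 6 vs 4 groups
datasets, truth = simulate_counts(cfg)
res = run_integration(datasets, RunConfig(lam=10.0, threshold=0.6, seed=1))

print("clusters per batch:",
      {b: a.n_clusters for b, a in res.assignments.items()})
print(res.pairs.pairs[["dataset_i", "cluster_p", "dataset_j",
                       "cluster_q", "similarity"]].round(3))
print(f"technical-variation ratio R = {res.basis.R:.4f}")

groups = truth.stacked_groups(["b1", "b2"])
batches = np.array(res.embedding.batch_ids)
L = res.embedding.L
spec = specificity(L, (batches == "b1") & np.isin(groups, [4, 5]))
shared = np.isin(groups, [0, 1, 2, 3])
print(f"specificity of batch-1-only groups = {spec:.3f}")
print(f"batch silhouette within shared groups = "
      f"{silhouette(L[shared], batches[shared]):.4f}")
```

Output:

```
clusters per batch: {'b1': 6, 'b2': 4}
  dataset_i  cluster_p dataset_j  cluster_q  similarity
0        b1          3        b2          1       0.966
1        b1          4        b2          2       0.974
2        b1          5        b2          3       0.991
3        b1          6        b2          4       0.985
technical-variation ratio R = 0.0041
specificity of batch-1-only groups = 1.000
batch silhouette within shared groups = -0.0003
```

Both batches are clustered correctly (6 and 4 putative clusters), the
four shared populations are matched one-to-one with similarity far above
T = 0.6, and the two batch-1-specific populations match nothing. In the
corrected embedding the shared populations mix across batches (batch
silhouette ≈ 0) while the batch-1-specific populations keep entirely to
themselves (specificity = 1): batch effects are removed without
over-alignment.

The same pipeline is available from the shell:

```bash
sccorrect simulate --preset s2 --seed 1 --out sim/
sccorrect integrate --data sim/b1:b1 --data sim/b2:b2 --seed 1 --out run/
sccorrect metrics --embedding run/embedding.tsv --labels labels.tsv --out scores.json
sccorrect project --basis run/basis.npz --data sim/b3:b3 --out new_embedding.tsv
```

## Documentation

See `docs/methods.md` for the model, its assumptions, parameter
defaults, numerical choices, what the simulator does and does not
emulate, and known limitations.
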