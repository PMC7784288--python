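# Methods

This note documents the model implemented in `sccorrect`, the choices
made where the design was genuinely open, and what the bundled
simulations do and do not establish.

## Model and assumptions

The central assumption is that, after per-dataset clustering, cell
clusters that can be matched across datasets represent the same
biological population, so any systematic difference between the matched
clusters is technical (batch) variation. Conversely, clusters that
match nothing are treated as dataset-specific biology and are never used
to learn the correction. This confines the risk of over-alignment to
the matching step: a wrong match converts biology into "technical"
variation and subtracts it, while a missed match merely leaves some
batch signal in place. The default similarity threshold T = 0.6 errs
toward missing weak matches rather than inventing them.

The correction is linear and global: one set of correction vectors V is
learned from all shared pairs and applied to every cell (including
cells of unmatched clusters and, later, entirely new datasets). The
method cannot remove nonlinear or population-specific distortions; it
trades that flexibility for the guarantee that dataset-specific
populations are never warped toward foreign ones.

## Pipeline stages and parameters

1. **QC** — features detected in < 3 cells and cells with < 200 detected
   features are dropped (features first, single pass). For the small
   simulated gene panels used in tests the cell threshold is exposed as
   `min_features`.
2. **Normalization** — per cell: counts / total × 10⁴, then ln(1 + ·).
3. **HVG selection** — per-gene Fano factor (variance/mean) on the
   log-normalized matrix; genes are ranked by mean expression and split
   into 20 equal-count bins; Fano factors are z-scored within each bin;
   genes with z > 0.05 and mean > 0.01 are kept. Equal-count (quantile)
   bins are used rather than equal-width so every z-score is estimated
   from the same sample size. The feature space for integration is the
   union of per-dataset HVG lists intersected with the features present
   in all datasets.
4. **scATAC gene scoring** — a peaks-by-cells matrix becomes
   genes-by-cells by summing peak counts whose midpoints lie within
   ±50 kb of a gene's TSS, weighted exp(−distance / 5 kb). The 5-kb
   decay scale is a configuration knob; distance is midpoint-to-TSS and
   strand is ignored for the symmetric window.
5. **Per-dataset clustering** — PCA (centered, unscaled, 40 PCs), kNN
   (k = 20, Euclidean in PC space), SNN weights |NN(i) ∩ NN(j)| / k
   (a Jaccard variant is available via `snn_jaccard`), Leiden at
   resolutions 0.1–0.5, consensus matrix of co-clustering frequencies,
   cluster number = count of singular values holding > 1% of the
   spectrum mass, final labels from an average-linkage cut of
   1 − consensus.
6. **Confident cells** — per cluster, cells whose mean within-cluster
   SNN weight strictly exceeds the cluster's Q₃ (the quantile cutoff
   generalizes to [0.5, 1)). If ties make the strict rule empty, the
   top max(3, 10%) cells are taken; a singleton cluster keeps its cell
   with a warning.
7. **Markers and matching** — per cluster, a two-part hurdle LRT on
   confident cells against all other confident cells of the same
   dataset: a binomial deviance for the fraction of expressing cells
   plus a normal deviance for mean log-expression among expressing
   cells, χ²(2 df). Thresholds: p < 0.05 (no multiple-testing
   correction, by design), natural-log fold-change > 0.25, expressed
   fraction > 0.25. Cluster-pair similarity = mean of marker overlap
   s/min(n₁, n₂) and cosine similarity of confident-cell mean profiles
   over the marker union (clipped to [0, 1]); pairs need similarity
   strictly > T. One-to-many matches are allowed.
8. **Correction** — for each shared pair the larger side is downsampled
   uniformly to n_pq = min(n_p, n_q); Y gets one column per matched
   cell pair (+1/−1), with **disjoint column blocks per pair**, so
   X̂ᵀYYᵀX̂ is exactly the sum of per-pair difference quadratic forms.
   X̂ is column-centered before the eigenproblem (the centering cancels
   in the technical term because Yᵀ1 = 0 per column); the same centering
   vector is stored and applied at projection time. Eigenvectors with
   strictly positive eigenvalues are kept (≤ k = 40), signs fixed by
   making each column's largest-magnitude entry positive. If no pair
   passes T, the pipeline falls back to the λ = 0 (PCA) embedding with
   a prominent warning rather than failing.

λ (default 10) controls how hard technical variance is subtracted; the
method is insensitive to moderate changes because the technical
directions carry large penalized variance while biological directions
are barely touched.

## Numerical choices

- The eigenproblem is solved in the m × m feature space (m = number of
  shared HVGs), the smaller dense side at this scale. In the λ = 0 /
  no-pairs limit a thin SVD of the centered X̂ is used instead of
  forming X̂ᵀX̂ — the same spectrum, better conditioned.
- Subsampling seeds derive from a CRC of the unordered pair identity
  plus the master seed, and the +1 side of each Y block is the
  lexicographically smaller (dataset, cluster) key, so the learned
  basis is invariant to the order in which datasets are supplied.
  Per-dataset Leiden seeds likewise derive from the batch id, not the
  input position.
- LISI bandwidths are calibrated by binary search on the Gaussian
  precision until the neighbor-weight entropy hits log(perplexity)
  within 1e-5 (≤ 50 iterations) over the 3 × perplexity nearest
  neighbors. The normalized scalar follows the
  (median − min)/(max − min) convention over per-cell scores, with
  empirical min/max; raw per-cell scores are available for diagnostics.
- The principal curve is initialized from the first principal
  component, smoothed by a running mean over a span of 30% of cells,
  condensed to ≤ 100 polyline nodes, and refit by orthogonal
  re-projection for ≤ 20 iterations (convergence when the mean
  projection displacement falls below 1e-4 of the curve length).
  Pseudotime is the arc-length position; only |r| is reported across
  fits because curve orientation is arbitrary.
- POS counts tied pairs as neither concordant nor discordant; Kendall
  tau is tie-corrected (tau-b). Rank-based overall scores give tied
  methods the mean of their point range.
- Confident-cell quantiles use linear interpolation (`np.percentile`
  default); ties exactly at Q₃ are excluded (strict inequality).

## The simulator

`sccorrect.simulate` draws gamma-Poisson counts: gene base means from
Gamma(0.6, rate 0.3), per-group DE factors (default: 8% of genes at
3× per group), per-batch lognormal gene factors (σ = 0.25; nested
designs multiply a set-level σ = 0.25 factor with sub-batch σ = 0.1
factors), lognormal(0, 0.2) library sizes, Poisson sampling. The
trajectory generator interpolates gene programs log-linearly along a
latent time t ~ U(0, 1); its preset uses a stronger program (30% of
genes, 4×) so that consensus clustering segments the continuum into
several putative clusters — matching the regime the method expects,
where matched segments across batches anchor the correction.

Six presets mirror common benchmark designs (equal compositions,
imbalanced 6-vs-4 compositions with 1,500 cells, three batches,
a trajectory, a 4,800-cell 8-group design, and 16 nested sub-batches);
the larger scenarios are deliberately kept at a few thousand cells so
the full pipeline runs in seconds on a laptop.

The simulator covers multiplicative batch effects, imbalanced and
absent populations, nested batches and continuous trajectories. It does
**not** model zero-inflation beyond Poisson sparsity, gene-gene
correlation, mean-variance (BCV) trends, doublets, or ambient RNA.
Passing tests therefore demonstrate the algebra and the pipeline's
behavior under clean multiplicative batch effects — not performance on
the full messiness of real data.

## Known limitations

- Matching relies on marker sets; datasets whose clustering collapses
  to a single cluster yield no marker contrast, and matching degrades
  to cosine similarity of whole-dataset profiles, which is unreliable
  on continuous trajectories (mitigated by the stronger trajectory
  preset, but a real dataset with no separable structure remains a
  hard case).
- The correction is a single linear basis; batch effects that differ
  per population are only removed in their shared component.
- The SNN weight uses the |∩|/k convention; Jaccard weights are
  available but not the default, and cluster numbers can shift slightly
  between the two.
- Consensus matrices are dense (n × n per dataset), which bounds
  practical per-dataset size to a few tens of thousands of cells.
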