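# Methods

This note documents the statistical model behind each pipeline stage, the
tunable parameters with their defaults and rationale, the scope of the
synthetic data generator, and the numerical conventions that make every
run deterministic. Quantitative performance statements are not made here;
they are computed by the test suite (`tests/`) and the acceptance script
(`scripts/acceptance.py`), which report them from actual runs.

## 1. Quality control and normalization

Per-cell metrics from the raw UMI matrix:

- `n_features` — genes with count > 0,
- `total_counts` — column sum,
- `mito_fraction` — fraction of counts on mitochondrial genes
  (symbols prefixed `mt-`, case-insensitive, or flagged explicitly).

A cell is kept when **all** of `min_features ≤ n_features ≤ max_features`
and `mito_fraction ≤ max_mito` hold. Both feature bounds and the
mitochondrial bound are **inclusive**: a cell sitting exactly on a
threshold survives. Defaults `min_features=200`, `max_features=2500`,
`max_mito=0.30` are the conventional droplet-scRNA-seq cutoffs for kidney
tissue — below 200 detected genes a droplet is likely empty or ambient,
above 2,500 likely a doublet, and above 30% mitochondrial content likely
a dying cell. Cells with zero total counts are flagged and always removed
(they cannot be normalized).

Normalization is library-size scaling followed by log transform:

```
value = ln(1 + count / total_counts × scale_factor)
```

with `scale_factor=10000`. The defining invariant, checked by the tests:
for every normalized cell, `Σ_genes (e^value − 1) = scale_factor` exactly
(up to floating-point rounding), i.e. de-logging recovers a common
library size.

## 2. Clustering and annotation

- **Highly variable genes** — top `n_top=2000` genes by variance of the
  normalized values, ties broken lexicographically by symbol so the set
  is deterministic.
- **PCA** — the HVG submatrix is z-scored per gene (`scale=True`;
  constant genes are left at zero rather than divided by zero), then
  projected onto `n_components=30` principal components via a full SVD
  (`svd_solver="full"` — the randomized solver would introduce
  seed-dependence). `n_components` is clamped to `min(n_cells, n_genes) − 1`.
  Component signs follow a fixed convention (the entry of largest
  absolute value in each loading vector is made positive), so the
  embedding is bit-reproducible.
- **Graph** — k-nearest neighbors in PC space (`k_neighbors=15`,
  Euclidean), symmetrized into a shared-nearest-neighbor graph with edge
  weight `shared / (k + 1)` where `shared` counts common neighbors
  (each node's neighborhood includes itself). 15 neighbors is the common
  default for datasets of a few thousand cells; SNN weighting
  de-emphasizes spurious long-range links.
- **Leiden** — RB-configuration modularity with `resolution=0.5` and an
  explicit `seed`. Cluster ids are relabeled densely by decreasing size,
  so cluster 0 is always the largest. Resolution 0.5 recovers
  structure at the granularity of major kidney cell types rather than
  sub-states.
- **Annotation** — for each cluster and each candidate cell type, the
  score is the mean (over the type's marker genes) of the z-score of the
  cluster's mean expression across clusters. The best-scoring type is
  assigned; if the best score is ≤ 0 the cluster is `unassigned`. This
  makes annotation invariant to marker-list order and robust to
  marker-panel size differences. Markers absent from the matrix are
  skipped with a warning.

## 3. Differential expression

Within each cluster, case vs. control cells are compared per gene with a
two-sided Mann–Whitney U test, asymptotic normal approximation with tie
correction and **no** continuity correction. When all values are tied the
statistic is degenerate and `p = 1` is reported. P-values are
Benjamini–Hochberg adjusted **within each cluster** (each cluster is its
own family of 1 test per gene). The effect size is

```
log2_fc = log2( (mean_case_delogged + ε) / (mean_control_delogged + ε) )
```

where the means are taken over de-logged normalized values (`e^v − 1`)
and `ε = 0.01` is a fixed pseudocount that keeps the ratio finite for
silent genes; a gene silent in one group against mean 1 in the other
yields `log2((1 + 0.01)/0.01) = log2(101)`. Clusters with fewer than
`MIN_CELLS_PER_GROUP = 3` cells in either condition are skipped — the
rank-sum null is meaningless below that.

## 4. Co-expression modules (WGCNA-style)

- **Pseudocells** — cells are stratified by (cluster, condition) and
  averaged in deterministic groups of `group_size=10` (cell order within
  a stratum follows the input matrix). Only **full** groups are kept;
  leftovers are dropped rather than forming a smaller, noisier
  pseudocell. Averaging reduces drop-out sparsity so Pearson correlation
  behaves.
- **Soft threshold** — for each candidate power β ∈ {1,…,20} the
  adjacency is `|cor|^β`; scale-free fit R² is the regression of
  log10(frequency) on log10(mean connectivity) over equal-width
  connectivity bins (`n_bins=10`), skipping bins with fewer than 2
  members (singleton bins carry no frequency information and destabilize
  the fit). The **smallest** β with signed R² ≥ 0.80 is chosen; if none
  qualifies, the argmax. Smallest-qualifying keeps sensitivity: higher
  powers shrink moderate correlations toward zero.
- **TOM** — topological overlap
  `TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`
  with unit diagonal; symmetric, bounded in [0, 1].
- **Modules** — average-linkage hierarchical clustering of `1 − TOM`,
  cut at static height `cut_height=0.99`; clusters smaller than
  `min_module_size=30` go to the `grey` (unassigned) pool. Modules are
  named `M1, M2, …` by decreasing size.
- **Eigengene** — first principal component of the per-gene standardized
  module submatrix, sign-aligned so it correlates positively with the
  module's mean expression profile (PC sign is otherwise arbitrary).
- **Module–trait** — Pearson correlation (with p-values) between each
  eigengene and binary (cluster × condition) membership indicators over
  pseudocells.
- **Hubs** — module membership `kME_g = cor(expr_g, eigengene)`; the top
  `top_k=25` genes by kME are reported as hub genes.

## 5. Ligand–receptor cross-talk

For every ordered cluster pair (sender, receiver), including self-pairs,
and every database ligand–receptor pair, an edge is accepted when all
three criteria hold **in the case condition**:

1. the ligand is detected (raw count > 0) in ≥ `min_fraction=0.5` of the
   sender's case cells, and the receptor in ≥ `min_fraction` of the
   receiver's case cells;
2. the ligand's case/control fold change in the sender is
   ≥ `min_fc=2.0` (inclusive), where fold change uses de-logged
   normalized means with the same `ε = 0.01` pseudocount as DE;
3. both genes have nonzero mean expression in their respective
   case populations.

Senders require cells in **both** conditions (the fold change is
undefined otherwise); condition-pure clusters are excluded as senders
with a warning. Receivers only need case cells. Genes absent from the
matrix contribute fraction 0, mean 0 and fold change 1.0 (with a
warning), so they can never form edges. Results are sorted
deterministically by (sender, receiver, ligand, receptor). Raising either
threshold can only shrink the accepted edge set (monotonicity is verified
by tests). Defaults mirror common practice: half-population detection and
a twofold induction are the minimum for a biologically credible signal.

## 6. Synthetic data generator

Counts are negative-binomial, generated as Poisson–Gamma mixtures:
`count ~ Poisson(Gamma(shape=r, scale=μ/r))` with dispersion
`r = 1/0.1 = 10`, i.e. variance `μ + 0.1 μ²`. The generator plants:

- `n_clusters=6` cell populations × `cells_per_condition=150` per
  condition, with distinct baseline expression programs over
  `n_genes=1500` genes;
- canonical kidney marker genes elevated in their home cluster
  (AQP1/LRP2/SLC13A1 → PT, NPHS1/NPHS2 → podocyte, etc.);
- three 50-gene co-expression modules driven by per-cell latent factors
  (`latent_sd=1.2`, alternating-sign loadings). The latent strength was
  calibrated so within-module pseudocell-level correlations are ≈ 0.7 —
  strong enough for module recovery, weak enough that adjacency and TOM
  are exercised nontrivially. Per-cell totals are kept flat so modules
  do not masquerade as library-size effects;
- 12 true ligand–receptor interactions (ligand fold change 4, detection
  fraction 0.9 — a `detection_margin=1.4` multiplier on the mean keeps
  the realized detection fraction above target despite sampling noise)
  and 20 decoys that each violate exactly one criterion (flat fold
  change, or sparse detection at fraction 0.2);
- `n_lowq_cells=40` QC-failing cells (low feature counts or high
  mitochondrial fraction) whose ids are recorded in the ground truth.

The truth object records cell→cluster, gene→module, planted failures,
and true/decoy interaction keys, so every stage can be scored.

**What the simulator does not emulate:** ambient RNA contamination,
doublets, batch effects, cell-cycle structure, gene-length or GC bias,
continuous differentiation trajectories, or UMI saturation. Clusters are
well separated by construction; the generator validates recovery logic,
not robustness to all real-data pathologies. With very small gene panels
the planted "healthy" cells can dip below the 200-feature QC floor —
configurations intended to keep all main cells QC-clean should use
generous gene counts (the defaults do).

## 7. Determinism and numerical conventions

- All randomness flows through `numpy.random.default_rng(seed)` /
  seeded leidenalg; no global RNG state is touched.
- PCA uses full SVD with a fixed sign convention; eigengenes are
  sign-aligned to the module mean profile.
- Tie-breaks are always explicit: lexicographic gene order for HVG ties,
  size-then-first-occurrence for cluster and module relabeling,
  deterministic sorts for all outputs.
- Replicate seeds (in the acceptance script and multi-seed analyses) are
  derived as `(seed × 7919 + offset) mod 2³¹`, keeping them in valid
  range for all seeded libraries.
- The end-to-end pipeline writes SHA-256 checksums of every output into
  its manifest; identical (config, seed) runs produce identical
  checksums, which the acceptance tests verify byte-for-byte.

## 8. Limitations

- The asymptotic rank-sum p-value is approximate for very small groups;
  the exact-enumeration comparison in the tests shows the orderings
  agree, but for n < 8 per group an exact test would be preferable.
- The static tree cut is simpler than dynamic tree cutting; modules of
  very unequal density may be merged or missed at a single height.
- Rarely, the scale-free criterion is not met at any small power on a
  simulated replicate and β escalates to a large value, dissolving the
  modules for that seed; this is why module recovery is assessed as a
  median over replicate seeds rather than per-seed.
- The crosstalk filter is criterion-based, not probabilistic: it reports
  no p-values or permutation nulls for edges.
- Module–trait correlations treat pseudocells as independent samples;
  pseudocells from the same cluster share structure, so the p-values are
  anti-conservative and should be read comparatively.
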