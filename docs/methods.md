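# Methods

## Scope and data model

`svfcomm` infers directed cell-type–to–cell-type communication from a
single droplet scRNA-seq count matrix plus two external knowledge tables:
a curated ligand–receptor (LR) pair list and a symmetric protein-
association score table in the STRING convention (integer `combined_score`
in [0, 1000]). Cell types come either from the built-in clustering or from
a user-supplied label file (e.g. annotated clusters). Each condition
(sample group) is analyzed as one network; cross-condition comparison is
descriptive and out of scope, as is ortholog mapping of the LR list — the
tables are expected already in the species' gene symbols.

## Preprocessing

**QC.** A cell is retained iff detected genes > `min_genes` (200),
detected genes < `max_genes` (6,500) and mitochondrial count fraction
< `max_mito_frac` (0.40). All three are strict inequalities, applied
exactly as worded; boundary cells (e.g. exactly 200 detected genes) are
removed. Mitochondrial genes are recognized by the `mt-`/`MT-` name
prefix, overridable by an explicit gene list. The filter is idempotent and
an all-cells-removed outcome is a warning, not an error.

**Normalization.** Log-CPM with scale factor 10⁶:
`x_ig = ln(c_ig / Σ_g c_ig × 10⁶ + 1)`. For every cell with a positive
total, `Σ_g expm1(x_ig) = 10⁶` exactly (float rounding aside); all-zero
cells stay all-zero rows. This identity is asserted in the tests as the
normalization oracle.

**Covariate regression and scaling.** Per gene, OLS residuals of the
normalized values on `[1, total counts]`, then z-scoring; residuals are
exactly orthogonal to the covariate, zero-variance genes map to zero
columns, and a constant covariate degenerates to plain z-scoring. Only the
total-count covariate is regressed; mitochondrial fraction is not (the
source analysis names only read counts as the confounder).

**Highly variable genes.** Genes are ranked by variance divided by a
binned mean–variance trend (20 equal-count bins by mean; a bin's trend is
its mean variance). A binned trend was chosen over loess parity with any
particular package — the ranking, not the smoother, is what matters
downstream. `n_top` defaults to 2,000 (unstated in the source; standard
practice). Ties break lexicographically by gene name, making selection
fully deterministic.

**PCA.** Full deterministic SVD of the centered scaled matrix, 30
components by default; component signs fixed by making each component's
largest-magnitude loading positive. Rank-deficient inputs return fewer
components with a warning; an entirely constant matrix returns one zero
component so the downstream graph still has an embedding.

**Neighbor graph and clustering.** Each cell's neighborhood is itself plus
its k = 20 nearest cells (Euclidean in PC space; distance ties broken by
ascending cell index via a stable sort). Edges carry the Jaccard overlap
of the two neighborhoods and are pruned below 1/15 — the Seurat SNN
convention; k and the pruning threshold are config-exposed since the
source names the step but not the parameters. Leiden optimization of
RB-configuration modularity at resolution 1.5 (seeded, iterated to
convergence) yields clusters labeled "0", "1", … by decreasing size.
Exact parity with any specific clustering implementation is a non-goal;
validation uses recovery of planted structure (adjusted Rand index ≥ 0.9
on well-separated synthetic types), not cluster-count matching, because
absolute cluster counts are notoriously version- and data-dependent.

## Communication network

**Fold changes.** For each gene and type: `mean_in` and `mean_out` are
means of the linear-scale (expm1) normalized expression over the type's
cells and over all other cells;
`fc = (mean_in + ε) / (mean_out + ε)` with ε = 1 CPM. The pseudocount
avoids division by zero and caps the fold change when the baseline is pure
dropout (mean_in 9, mean_out 0 → fc = 10). `frac_expressing` is the
fraction of the type's cells with a nonzero count. Types with fewer than 3
cells are excluded (warning). The type-vs-all-other-cells baseline within
one dataset was chosen because the source does not state its baseline;
analyzing each condition separately reproduces per-condition networks.

**Graph.** Tripartite: type → ligand edges exist iff the ligand is
"expressed" in the type (`frac_expressing ≥ 0.10` — boundary inclusive —
and `log2fc > 0`, both configurable) and carry `max(log2fc, 0)`; clamping
encodes that only enrichment drives communication (raw-FC weighting would
let depleted genes contribute). Ligand → receptor edges carry
`combined_score / 1000 ∈ [0, 1]`; pairs missing from the association table
get weight 0, so they annihilate their paths (logged). Receptor → target
edges mirror the ligand side.

**Weights and strengths.** A path's weight is the product of its three
edge weights — the product (rather than a sum along the path) makes the
association score act as a confidence multiplier and a zero score kill the
pair. Connection weight = sum of path weights per ordered type pair;
self-connections are computed and flagged but excluded from strength
summaries by default. Strengths satisfy Σ incoming = Σ outgoing = Σ
selected connection weights by construction, and connection weights equal
a brute-force triple loop over (pair, source, target) — both are asserted
in the tests.

## Permutation inference

**Null.** Cell-type labels are shuffled uniformly across cells, preserving
cluster sizes — the strictest null consistent with the network's inputs,
chosen because the source says only "network permutation testing". Per
permutation, fold changes are recomputed for the ligand/receptor genes
only and the weight matrix rebuilt; a vectorized engine (one-hot group
sums over a cached dense cells × LR-genes block) makes each permutation
two small matrix products and is verified in the tests to agree with the
graph route to machine precision. An alternative edge-shuffling null
(permuting which type carries each gene's fold-change profile) is
available behind `null_scheme="edge"` and is not the default. A
`work_budget` guard raises on workloads that would silently take hours.

**p-values.** One-sided (enrichment only — depletion is not a finding
here), with add-one correction: `p = (1 + #{null ≥ obs}) / (B + 1)`, so
p ∈ (0, 1] and ties count conservatively against the observed weight.
B defaults to 100,000; calibration tests use 1,000 and power tests 4,000.
Exact enumeration over all distinct label assignments replaces Monte Carlo
for tiny inputs and serves as the oracle for the Monte Carlo estimator.

**Adjustment.** Benjamini–Hochberg step-up across all ordered type pairs
of the network (Bonferroni via config); the source prints only "Padj".
Significance is strict: `padj < 0.01`, so `padj = 0.01` exactly is not
significant. One consequence worth knowing: with T types the smallest
attainable adjusted p is `T² / (B + 1)`, so B must exceed `T² / α` for
anything to be callable — with 4 types and α = 0.01, B = 1,000 can never
reject (min padj 0.016) while B = 4,000 can (0.004). The replicate power
analyses therefore use B = 4,000.

**Calibration diagnostics.** The reported p is discrete and conservative:
every connection with observed weight exactly 0 gets p = 1. Uniformity
checks therefore use the randomized probability integral transform
`u = (#{null > obs} + U·(1 + #{null = obs})) / (B + 1)`, which is exactly
Uniform(0, 1) under label exchangeability; `u` is diagnostic only and
never feeds significance calls. On 200 signal-free simulations the
Kolmogorov–Smirnov test accepts uniformity and the fraction of adjusted
calls at α = 0.01 is 0.

## Synthetic data generator

Counts are `NB(mean = lib_i · base_g · fold(g, t), size = θ)` in the
mean/size parameterization (`size` = inverse dispersion;
`var = mean + mean²/size`), so moment tests are unambiguous. Components:

- `base_g`: log-normal, default median 0.5 counts (log-mean ln 0.5,
  log-sd 1) over 1,200 genes → ≈ 1,000 total counts and ≈ 450 detected
  genes per cell, a modest droplet library.
- `lib_i`: log-normal with unit mean and CV = `libsize_cv` (0.3); applied
  inside the NB mean so counts stay genuine integers.
- 13 `mt-`-prefixed mitochondrial genes (the mouse protein-coding
  complement) rescaled to a 10% expected count fraction.
- `markers_per_type` (30) disjoint marker genes per type at
  `marker_fold` (6): enough separation that the types are genuinely
  distinct clusters — this is what "well-separated" means here. The null
  generator (`simulate_null_dataset`) forces marker folds to 1 and removes
  planted signals, so every gene's law is identical across types and
  labels are exchangeable.
- Planted signals multiply the ligand's mean in the source type and the
  receptor's in the target type; the generated knowledge tables contain
  each planted pair at its association score plus decoy pairs (default
  score 400) drawn from background genes — not mitochondrial, marker, or
  planted — so decoys are true negatives by construction.
- QC violators (5% of cells): half truncated to 50 detected genes, half
  with mitochondrial counts inflated to 3× the nuclear total (75%
  fraction), mirroring the three QC filters so filter tests have planted
  positives. The defaults target the standard 200/6,500/40% thresholds;
  simulations with small gene universes should scale `min_genes`
  accordingly.

Everything is driven by independent, reproducible substreams of one seed;
identical specs give bit-identical outputs. What the generator does *not*
emulate: gene–gene correlation beyond type structure, doublets, ambient
RNA, batch effects, or condition time-courses — so passing tests certify
the pipeline's statistical machinery, not robustness to those artifacts in
real tissue data.

## Problem sizes and determinism

Validation runs use 4 types at 60–500 cells/type, 200–1,200 genes,
B = 1,000–20,000 permutations, 200 null replicates for calibration and 50
for power; the whole suite completes in a few minutes on one core. Every
stochastic step (simulation, PCA sign convention aside, Leiden,
permutation) is seeded; the full pipeline writes a manifest of SHA-256
checksums and two runs with the same config and seed are byte-identical.

## Known limitations

- Connection-level inference only; per-LR-pair p-values are not computed
  by default.
- The fold-change baseline and path-weight combination are documented
  design choices, not claims of parity with any prior tool.
- BH across ordered pairs treats connections as exchangeable hypotheses;
  with very few types the discreteness of empirical p-values dominates
  (see the B vs α note above).
- The SNN/Leiden stage targets planted-structure recovery, not
  reproduction of any particular published cluster count.
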