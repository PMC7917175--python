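# Methods

`immunoscape` re-implements, as a tested library, a tumor immunotyping
workflow for bulk expression cohorts: nomination of candidate vaccine
antigens, discovery and cross-cohort validation of immune subtypes by
bootstrap consensus clustering, single-sample signature scoring,
co-expression module discovery, and a graph-learned "immune landscape".
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Expression preprocessing

Input matrices are genes x samples on linear FPKM scale.  Genes with a zero
value in strictly more than 50% of samples (`zero_fraction_max = 0.5`) are
removed, then values move to log2(FPKM + 1).  The strict inequality means a
gene zero in exactly half the samples is retained.  Duplicate gene rows are
collapsed by keeping the row with the highest mean — deterministic and the
common practice when probe-level duplicates survive mapping.

## Survival statistics

Kaplan-Meier, the log-rank test and Cox proportional-hazards regression are
implemented locally so their internals are inspectable and testable against
one another (`lifelines` serves as an independent cross-check in the test
suite only).

* Kaplan-Meier uses the product-limit estimator; at a tied event/censoring
  time the event is processed first (the censored subject stays in the risk
  set for that time).
* The two-group log-rank test uses the hypergeometric variance
  `d(n-d)·nA·nB / (n²(n-1))`; times with a single subject at risk contribute
  zero variance.  A k-group generalization (k-1 df) handles subtype-level
  comparisons.
* Cox regression maximizes the Efron-tie partial likelihood by
  Newton-Raphson with step halving, so the log-likelihood trace is
  monotone.  Convergence is declared when the gradient max-norm falls below
  1e-6 or the likelihood improvement is at machine-precision level.  The
  global score test at beta = 0 is reported; for a binary covariate and
  tie-free times it coincides with the log-rank chi-square, which the test
  suite asserts to 1e-6.  Efron is the default tie method (more accurate
  than Breslow; Breslow is available).
* Median splits send ties to the "low" arm (values strictly above the median
  are "high"); an all-equal vector is a degenerate-split error.
* Stage and grade enter multivariate models as ordinal integers 1..4.
* BH FDR is delegated to `statsmodels` behind local input validation.

## Antigen screen

The funnel intersects five per-gene criteria, evaluated lazily so each stage
only computes statistics for survivors of the previous one (funnel counts
are therefore non-increasing by construction):

1. overexpressed: tumor-vs-normal log2FC > 1 (log scale mean difference)
   and BH q < 0.01 from one-way ANOVA; direction must be up;
2. mutated: somatic mutation frequency above a configurable minimum
   (default: mutated in at least one sample);
3. OS-adverse: median-split log-rank p < 0.05 with the high-expression arm
   worse (Cox HR of the split indicator > 1);
4. RFS-adverse: same on relapse-free survival (skipped with a recorded
   warning if RFS is absent);
5. APC-correlated: purity-adjusted partial Spearman correlation with at
   least one antigen-presenting-cell infiltration score (macrophage,
   dendritic cell, B cell by default) positive with p < 0.05 (t
   approximation, n - 3 df).

Genes passing 1–2 whose median-split OS effect is significantly *protective*
(HR < 1) are excluded from the candidate list and reported separately.

## Consensus subtyping

Patients are clustered by PAM (BUILD + repeated best-improvement SWAP, ties
to the lowest index, hence fully deterministic) on 1 - Pearson distance
between expression profiles.  For each k in 2..10 and each of B resamples
(default 500; 100 in the scaled test conditions) a fraction `frac = 0.8` of
patients is drawn *without replacement*; the consensus matrix entry for a
pair is the fraction of co-draws in which they co-clustered.  Pairs never
co-drawn get 0 with a warning — practically impossible at the default B but
defined for tiny-B tests.

Model selection integrates the empirical CDF of upper-triangle consensus
entries: `A(k) = ∫ CDF_k`, `Δ(2) = A(2)`, `Δ(k) = (A(k) − A(k−1))/A(k−1)`.
The automatic rule takes the largest k with Δ(k) ≥ 0.05; a manual override
is supported and recorded in provenance.  Final labels cluster the
consensus *distance* 1 − M_k with PAM (hierarchical clustering available)
and are renamed IS1..ISk by descending size, ties broken by the
alphabetically smallest member.

## Cross-cohort validation

Discovery subtypes are summarized by per-feature mean centroids and
projected onto an independent cohort by highest Pearson correlation
(consistent with the 1 − Pearson clustering metric; Euclidean
nearest-centroid would not be).  Reproducibility is quantified by the
in-group proportion — the fraction of a subtype's samples whose nearest
*other* validation sample shares the subtype — and by the Pearson
correlation between discovery and validation centroids.  Ties in assignment
go to the lowest-index subtype and are logged; zero-variance samples are
left unassigned.

## Single-sample signature scoring

ssGSEA with weight exponent alpha = 0.25: per sample, genes are ranked by
descending expression (ties averaged); walking down the ranking, the score
accumulates the difference between a rank-weighted ECDF over in-set genes
(weights rank^alpha normalized within the set) and the uniform ECDF over
out-of-set genes.  Scores are optionally divided by the global max − min of
the whole matrix ("range normalization"), which preserves all orderings.
Because the score is rank-based *within* a sample, coherent shifts of a
large gene subset (e.g. an active module) perturb the ranks of every other
gene; even signatures of pure background genes therefore carry some
subtype signal in strongly structured cohorts.  The test suite accounts for
this by comparing aligned against null signatures pairwise over seeds
rather than expecting null sets to be flat.

## Co-expression modules

Unsigned adjacency |cor|^beta with beta = 4 (soft-threshold scans report the
scale-free fit index: connectivities binned into 10 equal-width bins, bin
density regressed on log10 mean connectivity; the index is R² signed by the
slope).  The topological overlap matrix is
`TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`.  Genes are clustered
by average linkage on 1 − TOM and cut statically: because TOM
dissimilarities saturate close to 1, the cut height is placed at a fraction
of the merge-height *range* (5th percentile to maximum — the
dynamic-tree-cut `cutHeight` convention) rather than at an ECDF quantile;
the deep-split setting 0..4 maps to fractions 0.95..0.75 (default 4 →
0.75).  Branches below `min_module_size = 30` genes are "grey"
(unassigned).  This static cut is a deliberate simplification of the
dynamic hybrid algorithm; on block-structured data it recovers planted
modules exactly, but on real dendrograms with nested shoulders it will
split less finely than the hybrid cut.

Module eigengenes are the first right singular vector of the
gene-standardized module submatrix, sign-oriented to correlate positively
with the module mean profile; modules with eigengene dissimilarity
1 − cor < 0.25 are merged iteratively (closest pair first, ties by
alphabetical name).  kME is the Pearson correlation of each gene with each
eigengene; hub genes are members with kME > 0.9.  Module prognosis runs a
univariate Cox on the eigengene, a median-split log-rank on the module mean
expression, and ANOVA of the eigengene across subtypes.

## Immune landscape

A DDRTree-style principal tree: minimize

    Σ_i ‖x_i − W z_i‖² + λ Σ_(k,k')∈tree ‖y_k − y_k'‖²
      + γ ( Σ_ik r_ik ‖z_i − y_k‖² + σ Σ_ik r_ik log r_ik )

over an orthonormal projection W (q ≤ 4 components, default 2), latent
coordinates Z, K centers Y (default min(n, 50)) and soft assignments R.
The entropy term is grouped under γ so that the R-step closed form
(row-normalized Gaussian kernel exp(−d²/σ)) is the exact block minimizer;
every step — R, minimum spanning tree over centers, the
Laplacian-penalized linear solve for Y, the Procrustes update of W and the
closed form for Z — exactly minimizes its block, so the objective trace is
non-increasing by construction and asserted per iteration in tests.
Defaults: λ = 1, γ = 10, σ = 0.01 × median pairwise latent distance at
initialization, Z initialized from principal components, centers by
k-means++ with a fixed seed.  λ trades tree rigidity against the data
scale: on features much smaller than typical log-expression magnitudes the
rigidity term dominates and centers collapse, so inputs are expected on
the usual log2 expression scale (the tests use fixtures of that scale).

Branches are maximal paths between tree nodes of degree ≠ 2; a subtype
occupying ≥ 2 branches with ≥ 10 samples each is split into lettered
subsets (A, B, ... by descending occupancy).  "Extreme location" groups
take the most separated leaf centers (greedy max–min selection), collect
samples whose best center lies on the leaf's terminal segment (each center
claimed by at most one group, so groups are disjoint), and compare survival
by multi-group and pairwise log-rank.

## Synthetic cohorts

The generator defines the study conditions under which every recovery
guarantee is stated.  Defaults mirror a realistic two-cohort design
(discovery n = 239, validation n = 103, 500 immune genes, k = 5 subtypes);
the recovery tests use the documented scaled conditions (n = 200, 300
genes, B = 100).

* **Expression** is built in log2 space — baseline per-gene means uniform
  on [2, 8]; subtype centroids are scaled orthonormal directions supported
  on a dedicated marker-gene block, row-centered, so every subtype pair is
  separated by exactly `delta` noise-SDs per gene (RMS over the gene
  universe; default delta = 5) and there is no net tumor-vs-normal shift;
  module genes share latent factors (loading 1.5 log2 units) whose means
  shift by subtype (a centered random pattern scaled by 2.0), making
  modules the subtype-informative programs; the remaining genes are pure
  noise (background), giving null signatures a true reference; i.i.d.
  Gaussian noise (SD 1) is added and everything is exponentiated to FPKM
  (2^x − 1), so preprocessing is genuinely exercised.  A few extra
  near-silent genes (log2 mean −1.5) exercise the zero-fraction filter.
* **Antigens**: six planted genes are overexpressed (+2 log2 vs normal),
  co-regulated through a shared latent program (loading 1.0) — as
  co-nominated oncogenic antigens are in practice — each contributing an
  adverse log-hazard of 0.7 per expression SD.  The shared program keeps
  the *marginal* median-split hazard ratio of each gene above 2 despite
  the frailty induced by the other planted effects; with six independent
  effects the marginal HR would attenuate toward ~1.8 and the screen's
  stated sensitivity would be unattainable at any conditional effect size.
  A seventh planted gene is protective (log-hazard −1.2) to exercise the
  favorable-exclusion path.  APC infiltration scores load on the mean
  antigen expression (0.6) with purity leakage (−0.2) and noise (0.4).
* **Survival** is exponential with per-sample hazard
  `h0 · exp(subtype effect + Σ gene effects + module effect)`
  (baseline 1/500 per day ≈ median 1 year); independent exponential
  censoring is calibrated by root finding so the expected censored fraction
  equals the target (default 0.3) under the realized hazards.  RFS uses the
  same structure at 1.5× hazard; 5% of RFS entries are blanked.  Subtype
  log-hazards default to (−0.7, −0.4, 0.6, 0.2, 0.3): two favorable
  subtypes, one clearly adverse.
* **Mutations**: per-sample gene draws with Poisson counts, subtype means
  (30, 35, 40, 80, 90) — the two "cold" subtypes carry the highest burden;
  planted antigens gain extra mutations at rate 0.3 per sample.  Variant
  classes are drawn from a fixed non-silent distribution.
* **Signatures**: one aligned set per module (≥ 90% module genes) and null
  sets drawn uniformly from background genes.
* All randomness flows from one integer seed through spawned
  `SeedSequence` substreams; identical seeds give bit-identical bundles,
  and a validation cohort drawn from the same model parameters shares
  centroids and modules but no samples.

What the generator does **not** emulate: negative-binomial count noise,
batch effects, copy-number structure, non-proportional hazards, or
informative censoring.  Passing recovery tests therefore demonstrate the
pipeline's correctness and calibration under a clean generative model, not
its robustness to real-data pathologies.

## Pipeline and determinism

Stages run in a fixed order (simulate/load → preprocess → screen → cluster
→ validate → score → modules → landscape → prognosis); each stage validates
its prerequisites at config time, writes TSV outputs, and logs shapes and
wall time.  `provenance.json` records the canonical config hash, the seed,
stages run and skipped, and SHA-256 hashes of every output; outputs carry
no timestamps, so an identical config and seed reproduces byte-identical
files.  Problem sizes in the test suite and acceptance script (n = 200
cohorts, B = 100 resamples, 200 Cox replicates, 20 screen seeds) are the
package's documented scaled study conditions.

## Known limitations

* The static module cut approximates the dynamic hybrid branch cut; deeply
  nested module structure will merge or go grey more readily.
* ssGSEA's rank compositionality (above) means "null" signatures are not a
  perfect negative control in strongly modular cohorts.
* The principal tree optimizes a non-convex objective; different seeds can
  land on different (all locally optimal) trees, and λ is scale-sensitive.
* Cox assumes proportional hazards; the generator satisfies it by
  construction, so these tests say nothing about misspecification.
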