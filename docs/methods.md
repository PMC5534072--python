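# Methods

This note documents the statistical models, the synthetic-data conditions,
and the numerical and design choices behind `brainomics`. Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Normalization

Size factors are median-of-ratios: factor_j = median over genes (with a
nonzero geometric mean across samples) of count_gj / geomean_g. Factors
are kept raw rather than renormalized to geometric mean 1, matching the
convention of the reference count-based DE tools. The variance-stabilizing
step is the log-like transform `log2(count / size_factor + 1)`
(pseudocount 1); downstream statistics are medians, ranks and residuals,
which are insensitive to the difference between this and spline-based
variance-stabilizing transforms at the cohort sizes used. An exact VST
replication is deliberately out of scope.

PRUA correction fits, per gene, an ordinary least-squares regression of
normalized expression on the covariate (with intercept) and replaces
values with residuals re-centered at the gene mean — re-centering keeps
indices on an interpretable expression scale. The result is exactly
orthogonal to the covariate (asserted to 1e-8). Both residualized and
unresidualized paths are exposed, since some analyses want raw values.

Row z-scores use the population (n-denominator) SD; zero-SD rows are set
to 0 and flagged instead of raising.

## Differential expression: the NB-LRT stand-in

The DE stage is a deliberately simplified stand-in for shrinkage-based NB
tools. Per gene, at a fixed dispersion α (variance = μ + αμ²):

- **Dispersion**: method of moments on size-factor-normalized counts,
  α̂ = max(0, (s² − μ̄)/μ̄²), computed within each diagnosis group and
  pooled by residual degrees of freedom (pooling across groups would fold
  genuine fold changes into α̂), then shrunk with weight 0.5 toward a
  fitted a₀ + a₁/μ̄ mean-dispersion trend. All-zero genes get α̂ = NaN and
  are excluded.
- **Fit**: log-link GLM with log size factors as offsets, full design
  (intercept + age + pH + PMI + PRUA + case indicator) and reduced design
  (drop the indicator), maximized by IRLS. The fitter is batched: all
  genes share the design matrix, so each iteration solves one stacked
  weighted least-squares system (weights μ/(1+αμ)), with step-halving when
  a gene's log-likelihood worsens, a 1e-10 ridge jitter against singular
  steps, convergence at |Δℓ| < 1e-8 or 100 iterations, and η clipped to
  ±30 to keep exp(η) finite. α = 0 uses the Poisson limit. Non-convergent
  genes are flagged and excluded from FDR adjustment.
- **Test**: LRT statistic 2(ℓ_full − ℓ_reduced) against χ²(1); log2FC from
  the case coefficient. Each disorder is contrasted against controls in a
  separate two-level model, matching per-disorder case/control reporting
  (a single 4-level factor model is the stated alternative; pairwise
  contrasts are what the per-comparison outputs require).
- **Independent filtering**: genes with baseMean < 10 (mean normalized
  count) or a non-convergent fit keep p but get no adjusted p; BH runs
  over the survivors.

There is no Cox–Reid adjustment, no Cook's-distance outlier filtering and
no fold-change shrinkage. The unit suite verifies the fitter against
statsmodels GLM (Poisson deviance differences to 1e-6 at α = 0;
fixed-α NB coefficients to 1e-4), and the acceptance suite verifies
calibration: on a null 24+24 cohort of 2000 genes the p < 0.05 rate must
land in [0.035, 0.065] and planted log2FC = 1 must be recovered within
±0.25 on average.

## Cell-type composition

A sample's index for a cell type is the **median** normalized expression
of that type's marker genes — robust to individual marker outliers.
Indices compared across patients are computed on residualized log-like
values. The proportion predictor, observed index / purified-tissue index,
is scale-dependent and only meaningful on a **linear** expression scale:
the mixing benchmark therefore uses raw counts (its libraries share an
equal total by construction; `normalize.scaled_counts` provides
size-factor-scaled linear values for the general case). Observed and
purified indices must always be on a shared normalization.

In-silico mixing down-samples each purified vector to
`round(weight × common_total)` reads **without replacement** (multivariate
hypergeometric via numpy's generator, so the output total is exact and
elementwise ≤ the input) and sums gene-wise. Binomial thinning would be a
faster approximation but changes the marginal distribution; exactness is
what makes the conservation assertions possible.

Two null-resampling schemes give empirical p-values with the add-one
convention (1 + #{null ≤ obs})/(1 + n), avoiding p = 0:

- **Size-matched random sets** for mixing-weight MSE: each replicate swaps
  every marker set for a uniform draw of the same size from expressed
  genes (excluding nothing but the observed set itself).
- **Expression-matched sets** for median fold change: each null gene
  matches a real member's baseMean within 5% relative tolerance, sampled
  without replacement within a null set; when a member has no candidate
  the tolerance doubles with a warning (or errors, per configuration).

`ls_deconvolve` solves min ‖x − Sw‖² s.t. w ≥ 0, Σw = 1 per sample by
non-negative least squares with the sum constraint as a heavily weighted
appended row — the standard reference-profile deconvolution used as an
independent cross-check on the index ratios.

## Peaks and proximity

Consensus peaks use **anchored filtering**: intervals of the first
(reference) set that overlap by ≥ min_overlap bp (default 1) with at least
one interval in every other set, i.e. chained `bedtools intersect -u`
semantics, which yield "a filtered reference peak list" rather than
fragment intersections; a base-level `region` intersection mode exists
behind a flag. All coordinates are 0-based half-open everywhere; a TSS at
t and a peak [s, e) are at distance 0 when s ≤ t < e, else
min(s − t, t − e) — unstranded, since only proximity matters. Distances
are computed with sorted starts and cumulative-max ends, making them
invariant to peak order and to fragmentation that preserves covered
bases (property-tested). Genes on peak-free chromosomes get undefined
distances and are excluded.

The sweep tests, at each threshold t (ties are "near": distance ≤ t), two
one-tailed rank-sum hypotheses — near genes have lower DE p-values, and
near genes have lower log2 fold changes (reduced expression in cases).
n_near is asserted monotone in t on every run; thresholds with an empty
side are reported as undefined rather than crashing.

## Rank statistics

Rank-sum tests use exhaustive enumeration of the null when the combined
tie-free sample size is ≤ 12, otherwise the normal approximation with
mid-ranks, tie correction and continuity correction; a two-sided statistic
at the exact null center reports p = 1 (symmetry) where the continuity
correction would not. Spearman p-values are exact (full permutation
enumeration, cached per n) for tie-free n ≤ 8 — the t-approximation
deviates from the exact null by up to ~0.06 at n = 5 — and use the
t-approximation above that, where enumeration is combinatorially
infeasible. PCA is SVD-based with centered (unscaled) features and a
deterministic sign convention (largest-magnitude loading positive); Ward
clustering is Ward.D2 on Euclidean distances (the modern convention; on
the fixtures used here the D/D2 topologies coincide).

## Integrated pathway enrichment

Gene-layer inputs are uncorrected DE p-values — the method ranks raw
evidence and multiplicity is handled once, at the pathway level, by BH
over the surviving pathways' combined p-values (whether the original
analysis adjusted further is unstated; BH is this package's choice). The
background for each pathway is the complement of its members among
measured features. The membership filter reads "greater than five genes"
strictly (≥ 6 measured genes) and ≥ 1 measured metabolite. Directionality
is not encoded: the layer tests are one-tailed for *small p-values*, not
for signed effects. Fisher's method combines exactly two layer p-values
(χ²(4)); zero inputs are clamped to the smallest positive float with a
warning, and underflowing outputs are clamped positive so results stay in
(0, 1]. Note the combination is only synergistic when both inputs are
below ≈ 0.2846 (the root of p(1 − 2 ln p) = 1): combining two p = 0.3
values gives 0.3067.

## Metabolomics

Per-metabolite group tests default to the two-sided Wilcoxon rank-sum
(consistent with the non-parametric comparisons used elsewhere in the
pipeline; Welch's t is available behind a flag), so results are invariant
to monotone rescaling of each metabolite. Technical replicates are
averaged per subject before testing to avoid pseudo-replication. Constant
metabolites get p = 1 and a flag. Top-k selection per comparison breaks
p-value ties lexicographically by metabolite id; the union is
log2(x+1)-transformed, z-scored per metabolite, and samples are
Ward-clustered. The ratio analysis correlates a per-sample metabolite
abundance ratio with the mean normalized expression of a gene pair by
Spearman; zero-denominator samples are dropped with a warning.

## The synthetic cohort generator

The generator is the package's study-condition definition, not a tuning
surface. Defaults:

- **Cohort**: 24 subjects per diagnosis group (CTL and SZ by default; BPD
  and MDD addable), one region, 2000 genes, 2 M reads per sample, NB
  dispersion α = 0.05 shared across genes — typical bulk RNA-seq values.
- **Tissue composition**: four brain cell types with base weights
  (neuron 0.50, astrocyte 0.25, oligodendrocyte 0.15, microglia 0.10);
  per-sample weights ~ Dirichlet with concentration 200 (neuron-weight SD
  ≈ 0.035). A configured neuron shift moves weight from neurons to
  astrocytes in affected groups — the planted composition phenotype.
- **Profiles**: log-normal baseline means (meanlog 2, sdlog 1.2) with
  per-type log-normal wiggle (sdlog 0.25); marker genes (2% of genes per
  type, disjoint) have their own-type mean set to specificity_fold × their
  maximum elsewhere, so the specificity ratio holds by construction. The
  mixing benchmark uses fold 50 to emulate "uniquely expressed" marker
  sets — at fold 8 the cross-contamination term (1−w)/fold alone exceeds
  a ±0.05 recovery band at w = 0.2.
- **Planted effects**: per-gene log2 effects per diagnosis multiply the
  expected counts of case samples; a TF-proximity effect adds a configured
  log2 shift to all genes whose TSS lies within a configured distance
  (default 1 kb) of the planted consensus peaks. Effect sizes have no
  empirical scale to copy and are chosen once to make recovery tests
  well-powered (e.g. log2FC = 1 at 24+24; TF effect −1 at 12+12).
- **Genome**: one synthetic 10 Mb chromosome; TSSs placed uniformly;
  a core of consensus peaks (default 40–60 peaks of 400 bp) appears in
  every replicate peak set with ±50 bp boundary jitter plus private
  peaks per set.
- **PRUA distortion**: observed counts are a binomial thinning of the true
  counts with per-gene retention PRUA^sensitivity_g, sensitivity ~
  U(0.5, 1.5). Retention exactly proportional to PRUA would be a pure
  depth change that size factors absorb completely, leaving the covariate
  inert; gene-level sensitivity (mean 1, so proportional on average) is
  the minimal model under which alignment quality biases individual genes,
  and it is what lets the design-with-PRUA-vs-without comparison show
  fewer confounded false positives. Per-diagnosis PRUA means can plant
  that confounding deliberately.
- **Metabolites**: a coupled metabolite is exp(2 + 0.5·m) where m is the
  standardized mean normalized expression of its source genes plus
  Gaussian noise scaled by noise_sd·sqrt(1/ρ² − 1) — at noise_sd = 1 the
  log-scale correlation is ρ; at noise_sd → 0 it tends to 1. Uncoupled
  metabolites are independent log-normals; per-diagnosis multiplicative
  2^shift effects can be planted for differential testing.

What the generator does **not** emulate: gene–gene co-expression beyond
shared cell-type composition, GC/length biases, batch structure, agonal or
medication effects (pH/PMI/age are inert metadata), isoform-level signal,
and technical replicate structure for expression. Passing tests therefore
demonstrate the statistical machinery recovers planted truth under the
stated noise model, not robustness to every artifact of real post-mortem
data.

## Problem sizes in the checked runs

The acceptance script and suite run the mixing benchmark at the printed
5,759,178-read library size with 1000 null sets; DE calibration at 2000
genes × 48 samples; the pathway-ranking and proximity-sweep rates over 100
seeds each (the sweep cohorts use 400 genes × 24 samples with 60 consensus
peaks); and the coupled-metabolite recovery over 15 replicate 40-sample
cohorts. The null-set count for the marker benchmark (1000 rather than
10,000) still resolves the 95% win-rate comparison while keeping the run
brief.

## Known limitations

- The NB-LRT stand-in reproduces (baseMean, log2FC, p, padj) in
  distribution but not the exact numerics of shrinkage-based tools.
- Empirical p-values are bounded below by 1/(n_null + 1).
- The proportion predictor ignores cross-contamination of marker signal;
  with markers that are merely enriched (low specificity fold) it is
  biased upward by roughly (1 − w)/fold.
- Consensus semantics are anchored on the first peak set; region
  intersection gives different (fragmented) output and is available
  explicitly.
- Whether gene- or transcript-level TSSs anchor distances is a data
  choice; the package models one TSS per gene and keeps the first record
  on duplicates (with a warning).
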