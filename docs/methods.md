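# Methods

## Overview

`conselem` implements an analysis pipeline for sequence-conserved
enhancer-like elements (ELEs) and their relation to complex-trait genetics:

1. **Element identification** — base-level intersection of H3K27ac and
   chromatin-accessibility peaks within a cellular context.
2. **Conservation classification** — each element is scored by the fraction
   of its bases lying inside gapless alignment blocks of a second genome and
   thresholded at minMatch 0.1 / 0.5 / 0.9 into LC / MC / HC classes, which
   nest inside the full (NC) set by construction.
3. **SNP annotation** — binary indicators a(j) = 1{SNP j inside ≥ 1 element},
   with Cramér's V / Pearson's R for annotation correlations.
4. **Heritability enrichment** — stratified chi²-on-LD-score regression with
   conditional annotations, jackknife SEs, enrichment and the standardized
   effect size τ*, DerSimonian–Laird meta-analysis, and generalized Deming
   concordance regression.
5. **Fine-mapping overlap** — PIP-threshold overlap fractions with one-sided
   exact binomial enrichment tests.
6. **Bayesian element prioritization** — an annotation-informed spike-and-slab
   model on GWAS summary statistics with LD, fit by variational inference,
   yielding enrichment Bayes factors and per-element association
   probabilities P₁.

A synthetic-data module generates every input, so the full pipeline is
testable end to end without external downloads.

## Element identification and conservation

Coordinates are 0-based half-open (BED). Peak intersection merges each input,
takes the base-level intersection, and merges the result into maximal
intervals. The conservation fraction of an element is (bases covered by
source-side alignment blocks) / (element length); an element joins the
level-m class iff this fraction ≥ m, and the retained record is always the
original source-genome interval. This is an explicit, deterministic
approximation of liftOver's minMatch remapping semantics: the liftOver
binary's split-region and target-side behaviors are not replicated, which can
differ in edge cases (e.g., a chain that remaps an element in several pieces).
Omnibus sets merge context-specific elements, with bookended intervals
merged, so the result is disjoint and the operation idempotent. TSS proximity
classes use inclusive boundaries: ≤ 200 bp → `proximal200`, ≤ 2 kb →
`proximal2k`, else `distal`; distance is measured from the nearest element
base. Chain files are decomposed into gapless blocks; negative query strands
are converted to forward-strand coordinates.

## SNP annotation

A SNP exactly at an element's `end` coordinate is outside (half-open
convention). The omnibus annotation equals the elementwise maximum of
per-context annotations; the test suite checks this identity exactly on 1,000
random fixtures. Cramér's V is the uncorrected √(χ²/n) for 2×2 tables.
Binary-annotation summaries use the population standard deviation
SD_a = √(q(1−q)), q = |a|/p, because τ* scales by SD_a.

## Stratified heritability regression

The per-SNP effect-size variance is modeled as
Var(β_j) = τ₀ + Σ_d τ_d·a_d(j); with n samples this implies
E[χ²_j] ≈ 1 + n Σ_d τ_d·ℓ(j,d), where ℓ(j,d) = Σ_k r²(j,k)·a_d(k) is the
stratified LD score (plain squared sample correlation, no small-sample
adjustment; configurable window in bases, or whole LD blocks by default).
The regression has a free intercept; weights follow the standard
heteroskedasticity/overcounting style
w_j = 1 / (ℓ_tot(j) · 2(1 + n·ℓ_tot(j)·ĥ²/p)²) with ĥ² from a first
unweighted pass. The free intercept also absorbs the small uniform inflation
from sample-correlation leakage across LD blocks, so block-restricted LD
scores leave the τ estimates unbiased (verified by the recovery tests).
SEs come from a delete-one-block jackknife over contiguous SNP blocks (200
blocks by default, scaled down below 2,000 SNPs). Enrichment
(h²_a/h²)/(|a|/p) and τ* = p·SD_a·τ_a/h² are recomputed per jackknife
replicate; the one-sided enrichment P tests the per-SNP difference
h²_a/|a| − (h²−h²_a)/(p−|a|) > 0, matching the contrast used for
meta-analysis. The all-SNPs annotation returns enrichment exactly 1.

At desk scale (2,000 SNPs) the jackknife of the *ratio* statistics
(enrichment, τ*) is heavy-tailed when a replicate's h² approaches zero; the
coefficient τ and the difference contrast are stable, which is why the
concordance demonstration regresses τ estimates.

Random-effects pooling is DerSimonian–Laird (via
`statsmodels.combine_effects`, with the moment estimate of between-study
variance truncated at zero, where it coincides with fixed-effect pooling).
Generalized Deming regression minimizes
Σ (y_i − a − b·x_i)² / (se_y,i² + b²·se_x,i²) by profile search over the
slope, with delete-one jackknife SEs; for constant SEs this reproduces the
classic closed-form Deming estimator (checked to 1e-8).

## Fine-mapping overlap

For each threshold t, f_in = fraction of annotated variants with PIP ≥ t,
f_all = fraction among all variants; both the difference and the ratio are
reported, with an exact upper-tail binomial P for enrichment. Thresholds are
inclusive (a documented choice; the convention is configurable). Methods
(e.g., two different fine-mapping programs) are never merged; QC flags are
consumed as boolean columns and applied as row filters.

## Bayesian model on summary statistics

Marginal effect estimates are modeled as jointly normal with mean
S·R·S⁻¹·β and covariance S·R·S (S = diag of SEs, R = block-diagonal
reference LD), combined with the prior

- β_j ~ π_j·N(0, σ_j²) + (1−π_j)·δ₀,
- π_j = (1 + 10^−(θ₀ + a_j·θ))⁻¹,
- σ_j² = σ₀² + a_j·σ².

R is estimated per LD block from reference genotypes, symmetrized, shrunk
toward the identity (weight 0.1 by default) and eigenvalue-floored at 1e-8.

Inference uses a fully factorized spike-and-slab variational family fit by
coordinate ascent; SNPs are updated in order of decreasing |z| within each
block. The ELBO is computed after every sweep and is non-decreasing (a
coordinate-ascent guarantee the tests assert); convergence is declared when
the relative ELBO change falls below `tol` (1e-8 by default; the validation
harness uses 1e-6). Additive likelihood constants that do not depend on the
hyper-parameters are omitted from the ELBO, so ELBOs are comparable across
grid points and models on identical data — exactly what the Bayes factor
needs. Up to 3 deterministic initializations (prior means, LD-ignoring
marginal posteriors, uniform 0.5) are tried and the best ELBO kept; grids are
additionally warm-started from the neighboring point, which keeps the fit
deterministic. For a single SNP the coordinate update reproduces the exact
two-component posterior; for blocks of ≤ 12 SNPs the per-SNP inclusion
probabilities rank-correlate ≥ 0.95 with exhaustive enumeration over all
sparsity patterns.

Hyper-parameters (θ₀, θ, σ₀², σ²) are handled by grid averaging with uniform
hyper-prior weights: posterior quantities are combined with weights
proportional to exp(ELBO). The default grid spans θ₀ ∈ [−4, −1] (5 points),
θ ∈ [0, 3] (4 points), and slab variances on a geometric ladder scaled to the
median squared SE (a causal SNP with slab variance k·median(se²) boosts its
expected χ² by ≈ k), 4 × 4 points. The enrichment Bayes factor is the ratio
of hyper-prior-averaged evidence between the enrichment grid and the
θ = σ² = 0 baseline; it is exactly 1 when the enrichment grid degenerates to
the null point.

P₁, the posterior probability that at least one SNP in an element is
associated, is computed per grid point from the factorized posterior as
1 − Π_j (1 − α_j) and then grid-averaged. The exact joint "at least one"
probability is not available under the factorized family; the product form is
the documented approximation. P₁ is reported under three annotation
configurations: baseline (B, a_j ≡ 0), all elements (N), and conserved
elements (H). An all-zero annotation in modes N/H triggers a warning and
collapses to B (enrichment parameters are unidentifiable without annotated
SNPs).

## Summary-statistic harmonization

GWAS rows are matched to the reference by SNP id; swapped alleles flip the
effect sign, strand-complement matches are resolved by complementing, and
strand-ambiguous (A/T, C/G) or irreconcilable SNPs are dropped, with a count
per exclusion reason.

## Synthetic data: what it emulates and what it does not

- **Peaks**: H3K27ac peaks placed uniformly with uniform lengths
  (200–1,000 bp default); each accessibility peak either coincides exactly
  with an H3K27ac peak (probability `overlap_frac`) or is placed disjointly
  in the following gap, so the expected H3K27ac base overlap equals
  `overlap_frac` and the degenerate settings 0/1 give empty/identical
  intersections exactly.
- **Alignment blocks**: block lengths drawn until the requested coverage is
  met (last block trimmed), then scattered with multinomial gaps; realized
  coverage is exact to rounding. Target-side intervals have equal lengths on
  a mirror chromosome.
- **Genotypes**: two latent Gaussian haplotypes per individual with AR(1)
  correlation ρ within LD blocks (independent across blocks), thresholded at
  the Hardy–Weinberg quantile of a uniform allele frequency. The realized
  minor-allele-frequency floor is enforced by toggling single alleles at
  random individuals for boundary SNPs, which slightly perturbs
  Hardy–Weinberg proportions there. ρ = 1 is supported as a degenerate test
  case (identical standardized genotypes within a block when frequencies are
  equal).
- **Effects/phenotypes/GWAS**: β from the spike-and-slab prior above;
  y = Xβ + ε with ε scaled so the SNP-explained variance fraction equals
  `pve` (pve = 0 means pure unit-variance noise); per-SNP least-squares
  slope, SE, and z from single-SNP regressions.
- **PIPs**: Beta-distributed with fixed concentration; the annotated-SNP mean
  is `enrich_ratio` times the background mean (capped at 1), so the
  enrichment holds exactly in expectation.

Not emulated: recombination-based haplotype structure (LD is blockwise AR(1),
not distance-decaying across blocks), allele-frequency/LD coupling,
population stratification, imputation error, sex chromosomes, and
signal-level peak heterogeneity. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
robustness to every artifact of real GWAS or epigenome data.

## Validation harness

The harness draws matched positive datasets (θ = 2 log10-odds enrichment and
σ² = σ₀², i.e., doubled slab variance for annotated SNPs) and negative
datasets (θ = σ² = 0) with θ₀ re-solved so both have the same expected
fraction of trait-associated SNPs; the noise scaling matches the phenotypic
variance explained. Four scenarios cross prop_causal ∈ {0.005, 0.02} with
pve ∈ {0.2, 0.5}; each contributes 50 positive + 50 negative datasets on
2,000 SNPs (20 AR(1) blocks of 100, ρ = 0.5, 1,458 individuals — the
reference-panel size the design emulates) with 100 disjoint two-SNP elements
(10% of SNPs annotated). One genotype matrix (hence one LD structure) is
shared by all datasets, as in reference-panel designs. Each dataset is fit in
mode H over a reduced 3 × 3 × 3 × 2 grid (θ₀ ∈ {−3, −2.25, −1.5},
θ ∈ {0, 1.5, 3}, σ₀²/median(se²) ∈ {8, 32, 128}, σ² ∈ {0, 32·median(se²)}),
chosen as the harness's own desk-scale sizing; elements are called at
P₁^H ≥ 0.9 and labelled true/false by whether they contain a SNP with a
nonzero simulated effect. Reported: the per-element false positive rate on
negative datasets (~20,000 null element-dataset pairs) and the false
discovery rate across all calls. The full harness runs in ~2.5 minutes on
one CPU. `scripts/acceptance.py` re-runs it from scratch and writes the FDR.

## Numerical choices and degenerate inputs

- Rank-deficient annotation designs raise an error naming collinear pairs.
- Monomorphic reference SNPs are excluded from LD-score sums with a warning;
  monomorphic SNPs in an LD block used by the Bayesian model raise an error.
- Enrichment is undefined (error) for empty annotations; the all-SNPs
  annotation short-circuits to exactly 1.
- The binomial test requires 0 < p0 < 1; thresholds and PIPs are validated to
  [0, 1].
- Non-convergence of the variational fit within `max_iter` is flagged on the
  returned solution, not raised.
- A single meta-analyzed study is returned unchanged.
- All generators are deterministic given their seed; the harness derives
  per-dataset seeds from `numpy.random.SeedSequence` spawn keys.

## Known limitations

- The liftOver approximation retains whole source intervals; it does not trim
  elements to their conserved segments, so conserved-class elements keep
  their original lengths.
- ELBO-based evidence is a lower bound; Bayes factors inherit the usual
  variational bias, which partially cancels between numerator and
  denominator on identical data but is not guaranteed to.
- The P₁ product form ignores posterior dependence between SNPs inside an
  element; with strong within-element LD it can over- or under-state the
  joint probability.
- Jackknife SEs of ratio summaries (enrichment, τ*) are unstable at desk
  scale when h² replicates approach zero.
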