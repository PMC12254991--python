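# Methods

## The model

`divgwas` fits a Bayesian multiple-marker regression (BayesB) to one or two
traits jointly.  Stacking the two trait vectors, the observation model is

    y_t = X_t b_t + W_t c_t + Z_t u_t + Σ_j z_j (δ_jt α_jt) + e_t ,  t = 1, 2

* `b` — fixed effects: month (5 levels, absorbing the intercept), sex
  (2 levels), parity order (2 levels); flat prior.
* `c ~ N(0, I ⊗ C)` — common-litter effects, one level per dam × parity,
  shared by full sibs; C is the 2×2 litter (co)variance matrix.
* `u ~ N(0, A ⊗ U)` — polygenic effects with A the pedigree numerator
  relationship matrix (tabular method; unknown parents are unrelated base
  individuals) and U the 2×2 polygenic (co)variance matrix.
* `z_j` — centered 0/1/2 dosage covariate of SNP j; `α_j` its substitution
  effect, `δ_jt ∈ {0,1}` the per-trait inclusion indicator.  Bivariately a
  locus occupies one of four configurations — null/null, trait 1 only,
  trait 2 only, both — with default prior mass 0.9982 on the joint null and
  (1 − 0.9982)/3 = 0.0006 on each of the other three.  Univariate runs use a
  two-state indicator with exclusion probability 0.9988.
* `e ~ N(0, I ⊗ R)` — residuals ordered by individual, R a full 2×2 matrix.

Nonzero effects are Gaussian, `α_j ~ N(0, G_j)`.  By default G_j is
locus-specific with a shared inverse-Wishart prior (classic BayesB); a
shared-G mode (BayesC-like) is selectable because either reading of a
per-locus subscript is defensible.  All (co)variance matrices carry
inverse-Wishart priors IW(ν, Ψ) with mean Ψ/(ν − p − 1); ν defaults to
p + 2 so the prior mean equals the supplied matrix, which is how externally
estimated variance components are meant to be plugged in.

## The sampler

Single-site Gibbs, one named seed per run, fully deterministic.  Per
iteration: (1) missing phenotypes are handled by drawing the missing trait's
residual from its conditional given the observed trait (data augmentation);
(2) fixed effects, scalar updates with flat priors; (3) litter pairs and C;
(4) polygenic pairs and U — A is inverted once and each animal's 2-vector is
updated from its full conditional, an O(m²) sweep that is exact and cheap at
desk scale (a joint factored draw of u would mix marginally better per
iteration but costs a dense solve per iteration; the single-site scheme was
measurably faster in this size range); (5) the locus sweep: for each SNP the
four-configuration posterior is computed with α_j integrated out
analytically under the marginal prior of the active components, the
configuration is drawn, active components come from their Gaussian full
conditional and inactive components from the prior conditional given the
active ones, so the G_j full conditional stays a one-observation
inverse-Wishart update; (6) R from its inverse-Wishart full conditional on
the (augmented) residuals.  The stored `alpha` is the masked effect (zero
wherever δ = 0); the stored residual satisfies
y − Xb − Wc − Zu − Σ z_j α_j exactly in every saved draw.

The default schedule is 470,000 iterations, 70,000 burn-in, thinning 40
(10,000 saved draws).  Tests and the acceptance script use 20,000 iterations
with 4,000 burn-in and thinning 10 at n ≈ 200–300, k = 2,000 — sizes chosen
so each statistical check retains its power while a full run stays in the
tens of seconds; they are the package's reference desk-scale conditions.

A note on exchangeability: permuting SNP columns leaves the posterior
distribution invariant, and every deterministic post-processing step (PPA,
window statistics) is exactly permutation-equivariant.  The sampled chain
itself is not sample-path equivariant under permutation because single-site
updates condition on the current state in locus order; the degenerate
forced-exclusion case (joint-null mass 1) is order-invariant and is tested
exactly.

## Window statistics and regions

One 1-Mb window is anchored at every SNP (half-open interval
[anchor, anchor + 1 Mb), never crossing a chromosome); windows whose member
set repeats the previous anchor's are flagged as duplicates.  Per saved draw
the window genetic value of an individual is Σ_{j∈w} z_ij α_j; the window's
share is its across-individual variance over the variance of the
whole-genome marker value of the same draw, ×100.  The default denominator
is markers-only; a markers+polygenic mode adds u to the total.  Draws with
zero total variance contribute nothing; a window with no included member in
a contributing draw has share 0 there.  Windows whose posterior-mean share
reaches 0.75% of the genetic variance are associated; overlapping associated
windows merge into regions (start = first member SNP of the first window,
end = last member SNP of the last).  The region PPA is the fraction of saved
draws in which at least one member SNP is in the model for the trait — the
summary tables print one PPA per region without a printed definition, so the
any-member convention is this package's documented choice.  The window
genetic correlation is the per-draw Pearson correlation across individuals
between the two traits' window values, skipping draws where either variance
is zero; a region reports the constituent window correlation largest in
magnitude (sign retained) together with its SD, and the per-window values
remain available for the alternative reading.

## QC and the divergence screen

SNP filters: known autosomal position, call rate ≥ 0.95, MAF ≥ 0.05 on
observed calls (ties kept).  Animal filters: more than 3% missing genotypes
(strictly above) and a Mendelian-inheritance screen — the per-animal rate of
opposing-homozygote conflicts against each genotyped parent, failing above
1% of comparable SNPs; only the offspring is removed, the parent kept.  The
1% statistic is this package's choice of trio-conflict screen; the source
protocol names the test but not its statistic, so the threshold is
configurable and recorded in the report.  Remaining missing calls are filled
per SNP by rounded expected dosage (or sampled under Hardy–Weinberg in
stochastic mode); this is deliberately not haplotype imputation and is
flagged as such in the log.

The variant screen keeps moderate/high-impact coding consequences (missense,
frameshift, start lost, stop gained, conservative inframe indels), computes
per-line alt-allele frequencies over called genotypes only, and retains a
variant when (1) an allele is fixed (exactly 1.0 — no near-fixation slack)
in one line while that same allele is below 0.5 in the other, or (2) one
allele exceeds 0.65 in one line while the alternative allele exceeds 0.65 in
the other (both strict).  Both criteria are symmetric under line swap and
ref/alt recoding.  A variant fixed in one line but at 0.6 in the other fails
criterion 1 by construction.

## The synthetic-data generator

`simdata.simulate` founds a base population with per-SNP allele frequencies
uniform on [0.1, 0.5], splits it into a high and a low line, and breeds a
configurable number of generations with truncation selection on trait 2
(IMF-like), 10 sires and 40 dams per line by default (~240 progeny per line
per generation).  Meiosis uses a uniform 1 cM/Mb map with Haldane's mapping
function — a neutral default, not a rabbit linkage map.  Phenotypes follow
the analysis model exactly: month cycles over litters within generation, sex
is Bernoulli(½), parity is Bernoulli over two levels per litter, full sibs
share a litter draw, polygenic values descend the pedigree with Mendelian
sampling variance U/2 (inbreeding-adjustment of the sampling variance is
omitted; at these depths the overdispersion is negligible), and residuals
are drawn with correlation `r_e`.  All variance parameters are fractions of
a unit founder phenotypic variance: defaults h² = (0.35, 0.50),
c² = (0.10, 0.10), polygenic correlation 0.3, residual correlation 0.2 —
realistic magnitudes for carcass/meat-quality traits and an IMF-like
selection criterion in a species like the rabbit.  QTL entries
(chrom, bp, f₁, f₂, ρ) are calibrated against the realized founder dosage
(co)variances, so the founder-cohort genetic (co)variance of each entry
matches its target exactly.  A genetic correlation with both fractions
positive and |ρ| < 1 is not realizable by one marker (a single locus gives
correlation ±1), so such entries expand into a pair of neighbouring causal
markers within one window whose summed contribution has exactly the
requested correlation; ρ ∈ {−1, 0, 1} or single-trait entries stay single
markers.  A `hide_qtl` mode drops the causal columns to emulate LD-only
detection.

What the generator does not emulate: real linkage maps and assembly
coordinates, site-frequency spectra of array SNPs (no ascertainment bias),
genotyping error (QC inputs are clean unless corrupted by the caller),
maternal genetic effects, and overlapping generations.  Passing tests
therefore demonstrate correctness of the machinery under the stated
generative model, not robustness to real-data artefacts.

## Numerical choices

* A is factored by Cholesky with a clipped-eigendecomposition fallback for
  semi-definite matrices (tolerance 1e-8 on reconstruction); A⁻¹ is computed
  densely once per run, with a diagonal jitter ladder only if singular.
* The locus sweep is hand-scalarized 2×2 algebra (numba), avoiding
  allocation in the k × n_iter hot loop; inverse-Wishart draws use the
  Bartlett decomposition.
* Configuration scoring subtracts the maximum before exponentiating;
  degenerate zero-variance covariates score all configurations at their
  prior mass.
* Ties in selection ranking break by animal id (deterministic); mating is
  round-robin with full-sib-pair avoidance when possible.
* Zero prior masses are floored at 1e-300 inside the log only; a mass of
  exactly 1 on the joint null forces all indicators to zero.
* Thresholds compare with the printed inequality directions: `≥` keeps at
  call-rate/MAF/window thresholds, "more than" removes strictly above at
  animal missingness, and the divergence criteria use exact fixation and
  strict 0.65.

## Known limitations

* Dense A and O(m²) polygenic sweeps target pedigrees up to a few thousand
  animals; larger pedigrees would want sparse A⁻¹ machinery.
* Per-locus G_j matrices are summarized in the saved draws by their
  across-locus mean; the full k × 2 × 2 per-draw array is not stored.
* With a markers-only denominator, window shares in draws with very little
  total marker variance are noisy; the posterior mean is reported over
  contributing draws and the contributing-draw count is exposed.
* The univariate/bivariate agreement check uses the product-form inclusion
  prior; under the default coupled prior (joint mass 0.0006 on the "both"
  configuration, far above the product of the marginals) the bivariate model
  deliberately shares evidence between traits, which is its point.
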