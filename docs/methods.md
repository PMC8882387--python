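# Methods

## Model

`mkomega` implements a maximum-likelihood McDonald–Kreitman extension in
which the distribution of fitness effects (DFE) of new nonsynonymous
mutations is a gamma distribution over deleterious scaled effects only
(shape β, mean s̄ = −E[4N_e s]; the "GammaZero" family).  Synonymous
mutations are neutral.  Observed SFS counts are treated as independent
Poisson draws around the Poisson-random-field expectations

    E[syn_i]    = L_S · θ · r_i / i
    E[nonsyn_i] = L_N · θ · r_i · Φ_i(β, s̄),   Φ_i = E_s[F(i, n, −s)]

where F integrates the semidominant diffusion sojourn density against
binomial sampling.  The per-frequency-class multipliers r_i (r_1 ≡ 1,
shared between site classes) absorb demography and ascertainment
distortions, which is what makes the method robust to non-equilibrium
histories: any distortion common to both site classes cancels from the
information that identifies the DFE (the synonymous/nonsynonymous ratio
within each frequency class).

The DFE is estimated from polymorphism alone.  Divergence enters only
through dN/dS when the rates are derived:

    ω_na = E_s[s/(e^s − 1)],   ω_a = dN/dS − ω_na,   α = ω_a/(dN/dS).

The identities ω_a + ω_na = dN/dS and α·dN/dS = ω_a hold exactly by
construction on every fit.  ω_na ∈ [0, 1] for any purely deleterious DFE,
equals 1 in the neutral limit, and is strictly decreasing in s̄.

### Assumptions worth keeping in mind

* No beneficial mass in the DFE: weakly advantageous mutations, if
  present, inflate ω_a.
* The DFE is shared by all genes in a pool.  Pooling genes with
  heterogeneous s̄ makes the single fitted gamma an effective mixture
  compromise; on strongly heterogeneous pools ω̂_na can shift by a few
  hundredths, with the opposite shift appearing in ω̂_a.  This mirrors the
  behavior of the estimator on real pooled data and is visible in the
  package's own synthetic defaults.
* Divergence-phase and polymorphism-phase effective population sizes are
  equal.  The generator's `contraction_factor` decouples them to
  demonstrate the population-size-change artifact: if a factor correlates
  with the mean strength of selection, a contraction induces an
  artifactual correlation between that factor and ω_a.

## Numerics

F(i,n,S) has the closed form n/(i(n−i)) · (₁F₁(n−i;n;s) − 1)/(e^s − 1)
with s = −S (Kummer's confluent hypergeometric function).  Three branches
keep it stable: a second-order Taylor ratio for s < 10⁻³ (cancellation),
direct ₁F₁ for s ≤ 400, and the terminating asymptotic series of
₁F₁(n−i;n;s) for s > 400 (no overflow for arbitrarily large s).  The
branches agree to ~10⁻⁸ at the cut points and match adaptive quadrature of
the defining integral to ~10⁻¹⁴.

The gamma expectation Φ_i uses a fixed composite Gauss–Legendre grid in
log s (10⁻⁸ … 10⁹, 8 nodes per decade) with the F table precomputed per
sample size; mass below the grid is added analytically as CDF(s_min)/i
since F → 1/i as s → 0.  Validated to ~10⁻⁷ relative accuracy against
adaptive quadrature across β ∈ [0.03, 2.5], s̄ ∈ [10⁻³, 10⁶]; one
evaluation costs microseconds, which is what lets the test suite run tens
of thousands of fits.  `omega_na_from_dfe` uses adaptive quadrature split
at the DFE's quantiles (tolerance 10⁻¹⁰); the kernel's grid version agrees
to ~10⁻⁷ and is used inside fits.

### Fitting

With r_1 ≡ 1, each remaining r_i (distinct up to class 10, one shared
tail multiplier above — bounding the parameter count at large n) and θ
have closed-form Poisson MLEs given (β, s̄): the model is saturated in the
per-class totals, so the likelihood is profiled down to two dimensions.
L-BFGS-B runs on (log β, log s̄) with bounds β ∈ [0.02, 3], s̄ ∈ [10⁻⁴,
10⁶], from a central start plus seeded Latin-hypercube starts over
β ∈ [0.05, 2], log₁₀ s̄ ∈ [0, 5] (5 starts by default).  The profiled
surface is smooth and in practice unimodal; bulk analyses in the test
suite use 2 starts.  Folded spectra are supported by folding the
expectations (r_i then indexed by minor-allele class).  Fits require
nonzero synonymous polymorphism and at least one singleton (θ is profiled
from the singleton class).

Percentile bootstrap CIs resample genes with replacement (same size as
the input), 100 replicates by default.

## Synthetic worlds

The generator emulates the statistical structure of a hominid coding data
set; its defaults are the package's reference conditions.

* **Covariates.**  Gaussian copula over (log recombination rate, gene
  age, log expression, log protein length).  The published gene-level
  correlation targets (age–expression 0.87, age–length 0.86, age–RR
  −0.62, expr–length 0.44, expr–RR −0.035, length–RR 0.10) do not form a
  positive-definite matrix — the age row alone forces expr–length ≥ 0.5 —
  presumably because they were estimated pairwise on different gene
  subsets.  The default keeps the three strong age-row entries exact and
  uses the minimum-distance PD completion of the rest (expr–length 0.785,
  RR–expr −0.319, RR–length −0.249).  `nearest_correlation` (Higham
  projection) is offered for user matrices.
* **Margins.**  Lognormal RR (median 1.2 cM/Mb), expression (median 8,
  TPM-like) and length (median 430 codons), with log-scale sigmas chosen
  to reproduce raw coefficients of variation near the reported 1.1–1.7.
  Age is an ordinal phylostratum 1..19 (1 = oldest, geometric skew toward
  old genes).  Analyses use the age score K+1−stratum, which increases
  with age, so correlation signs read conventionally.
* **DFE link.**  log s̄ = intercept + Σ slope_j · z_j over standardized
  log covariates; default slopes (age 0.45, expression 0.5, RR 0.7,
  length 0.2) make selection stronger on old, highly expressed, long,
  high-recombination genes.  The RR slope must exceed ~0.5 to dominate
  RR's negative correlation with age; the defaults yield negative
  bin-level correlations of ω_na with all four factors and positive
  correlations of log s̄ with all four, matching the observed directions.
  The intercept is calibrated by root-finding so the *site-weighted* mean
  ω_na equals 0.19 (what a pooled genome-wide fit reports).  β defaults
  to 0.4; the global adaptive rate defaults to ω_a = 0.04.
* **Counts.**  θ = 10⁻³/site, synonymous divergence 0.012/site; SFS
  counts are Poisson around expectations distorted by r_i = 1 + 0.3 ·
  exp(−(i−1)/4) (singleton excess 1.3 decaying to 1), which the
  estimator's nuisance terms are designed to absorb — demography is
  emulated phenomenologically, not by coalescent simulation.
* **Annotation.**  GO memberships per gene are Poisson (mean 2, zeros
  allowed) over 50 flat categories, or an exact count for balanced
  designs; VIP flags are Bernoulli(0.13).  VIPs get ω_a × 1.6 and
  s̄ × 2^(1/β) ≈ 5.66 by default, reproducing the observed contrast
  directions (higher adaptive, roughly halved nonadaptive rate).  Additive
  per-category and ±δ VIP effects on ω_a support variance-partition
  benchmarks with exactly known components.
* **Mutation classes.**  Counts split multinomially into WW/SS/WS/SW with
  fractions (0.08, 0.12, 0.35, 0.45), so the gBGC-insensitive restriction
  keeps ~20% of the data; site totals are partitioned deterministically
  (largest remainder) so restricted rates stay per-site comparable — how
  site counts should be renormalized under the restriction is otherwise
  unspecified, and this is the package's choice.  A `ws_fixation_bias`
  multiplier inflates weak-to-strong fixations only, emulating the gBGC
  artifact (inflated full-data α, unaffected WW+SS α).

What the generator does *not* emulate: linkage (SFS counts are
independent Poisson draws, so Hill–Robertson interference exists only
through the imposed covariate links), real GO topology, gene structure,
or mutation-rate variation along the genome.  Passing tests therefore
demonstrate correctness of the estimators and study designs under the
model's own assumptions, not robustness to linked selection.

## Study-design procedures

* **Binned correlations.**  20 near-equal quantile bins (ties broken by
  gene id; sizes differ by ≤1) or one bin per age stratum; per-bin pooled
  fits; Pearson r between the response and log₁₀ bin-mean factor (linear
  transform optional), p from the t distribution on n_bins − 2 df.  No
  multiple-testing correction is applied.
* **Modal control.**  Mode of the log₁₀ cofactor located as the midpoint
  of the tallest Freedman–Diaconis histogram bin; genes within ±0.5 SD
  kept; raw-scale CV before/after reported.  The FD mode estimator and
  the inclusive dN window [0.002, 0.007] are implementation choices.
* **Predicted correlation.**  r_YX expected from a shared confounder Z is
  r_YZ·r_XZ.  Significance by bootstrap: genes resampled within fixed
  X-bins, per-replicate observed and predicted correlations compared; the
  reported proportion of replicates with predicted/observed > 1 is read
  like a p-value.  Note that at the bin level a covariate strongly
  correlated with X at the gene level becomes almost deterministic in X,
  driving the predicted value toward the observed one — bin-level and
  gene-level correlations are not interchangeable.
* **Shuffle test.**  Statistic: unweighted variance of per-category point
  estimates over categories with >100 genes.  Null: each gene's data
  block (sites, spectra, substitutions, class split) permuted across gene
  labels with annotations fixed, preserving the overlapping-membership
  covariance exactly; p = (1 + #{null ≥ obs})/(N + 1).  The choice of an
  unweighted variance statistic is the package's.
* **Variance partition.**  (VIP × GO) cells pooled, downsampled to equal
  combined site totals (200,000 by default) with a multivariate
  hypergeometric, split into halves of equal site count, fitted, and fed
  into a two-way random-effects ANOVA (2 × G × 2).  Method-of-moments
  components with the interaction mean square as the subtrahend for the
  main effects (the error-mean-square variant is also reported since the
  convention is ambiguous); negative estimates truncate at zero, and the
  VIP/GO ratio is flagged undefined when σ²_GO truncates.  Undersized
  cells are dropped (without-replacement sampling cannot enlarge them).

## Problem sizes in the test suite

The acceptance-style tests run the full designs at reduced scale chosen
for desk-class hardware: estimator recovery on ≥2×10⁶ sites per class;
confounded-correlation calibration on 200 worlds of 1,200 genes with 8
bins; shuffle-test calibration on 100 worlds of 1,500 genes with 19
shuffles (permutation p-values on a 0.05 grid remain exactly valid); gBGC
direction tests on 20 worlds.  The acceptance script uses the full
15,500-gene default world.

Two benchmark designs deliberately carry more information per site than
the human-like defaults, because their purpose is to measure the power
and calibration of a *design*, not to mimic one data set.  A sample of 40
chromosomes holds ~3× less SFS information per site than a genome-scale
study sample, so (i) the VIP-detection worlds (100 worlds, 14,000 genes,
fixed ω_a × 1.6 VIP effect) raise per-site θ to 4×10⁻³ and divergence to
0.025 to restore study-scale aggregate counts; (ii) the variance-ratio
benchmark (100 balanced worlds, 4,800 genes, 12 single-membership
fixed-effect categories) likewise, with effect sizes set in the ANOVA's
own estimand convention — for fixed effects the random-effects
method-of-moments estimand is Σeffects²/(levels−1), i.e. 2δ² for a ±δ
two-level axis and G/(G−1)·Var(effects) for the category axis — so that
the true VIP/GO component ratio is exactly 5, and with a baseline ω_a
high enough that no cell's true rate clips at zero.

## Known limitations

* The fitted gamma is an effective DFE for a pool; per-gene DFEs are not
  identifiable at realistic polymorphism levels.
* log s̄ estimates from small bins are noisy and β/s̄ trade off along a
  likelihood ridge; mean-strength correlations are only reliable for
  well-populated bins.
* Fractional (projected) spectra are accepted by the likelihood as
  Poisson means but are only meaningful in expected-value analyses.
* The DOFE export rounds real-valued (degeneracy-weighted) site counts to
  integers.
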