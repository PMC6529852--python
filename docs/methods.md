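# Methods

This note documents the models, estimators, generator and numerical
choices behind `mrmediate`, and what its tests do and do not establish.

## The causal system

The package targets mediation questions of the form

    instruments → exposure X → mediators M₁…M₃ → binary outcome Y

with an unobserved confounder U of the exposure–mediator–outcome
relationships. The canonical instantiation is education (per SD of
schooling years) acting on cardiovascular disease through BMI, systolic
blood pressure and a lifetime smoking index. All binary-outcome effects
are carried on the log-odds scale; odds ratios appear only in rendered
reports. Mediation algebra on the odds-ratio scale is avoided because the
odds ratio is non-collapsible; on log odds with a rare outcome the
decomposition total = direct + Σ indirect is a good approximation and is
exact in the generator's linear predictor.

## Estimators

**Wald ratio.** β̂ = β̂_ZY/β̂_ZX. First-order delta SE σ_Y/|β̂_ZX| (the
default for IVW weights, matching the convention of standard two-sample
tooling); second-order SE adds the exposure-side term
β̂_ZY²σ_X²/β̂_ZX⁴ and is available for single-SNP reporting.

**Fixed-effect IVW.** Inverse-variance weighted mean of the per-SNP
ratios; with first-order weights this is exactly weighted least squares of
outcome betas on exposure betas through the origin with weights 1/σ_Y².
Both views are implemented as one computation and cross-checked in tests.

**MR-Egger.** Weighted regression with intercept, instruments oriented so
exposure betas are non-negative. SEs carry a multiplicative overdispersion
factor max(1, √(RSS_w/(k−2))); a strict fixed-effect toggle exists. The
intercept test uses a t distribution with k−2 df; every other interval
uses the Normal quantile 1.959964, consistent with summary-data
asymptotics.

**Weighted median.** Ratios sorted against cumulative-weight midpoints
q_j = Σ_{i≤j}w_i − w_j/2 and interpolated at 0.5. The SE is the standard
deviation over parametric resamples of (β̂_ZX, β̂_ZY); the seed is
mandatory, making every run reproducible. Default 1000 resamples
(100 minimum).

**Multivariable MR.** Weighted least squares of outcome betas on the
matrix of exposure betas, no intercept, weights 1/σ_Y², overdispersion as
for Egger. Exposure columns that are exactly zero are excluded from the
solve and reported as null with infinite SE (so a degenerate "mediator
with no instruments" collapses gracefully to single-exposure IVW); rank
deficiency among informative columns is an error naming the collinear
exposures.

The exposure-beta matrix is itself estimated, and its known sampling
variances σ_X² act like classical measurement error: they inflate the
weighted Gram matrix and attenuate coefficients (regression dilution
inside MVMR). `mvmr_fit(..., subtract_exposure_noise=True)` subtracts
Σ_j w_j·diag(σ_X,j²) from X'WX before solving — a standard
errors-in-variables correction that is consistent as panels grow. The
plain regression form remains the default (it is the conventional
estimator); the recovery pipeline uses the corrected form because its
instrument panels are deliberately realistic in strength, where the
dilution is a few percent of the coefficient and visible in the combined
difference method. SEs are taken from the corrected normal equations;
residual first-stage noise makes them mildly approximate, which matters
little next to the overdispersion scale.

**Mediation constructions.** Product of coefficients per mediator:
indirect = a·b with Sobel SE √(a²σ_b² + b²σ_a²) (no covariance term —
the two estimates come from non-overlapping or weakly overlapping
sources). Proportion mediated P = indirect/total with a gradient delta SE
var(P) = (σ_I/T)² + (I·σ_T/T²)², well defined at I = 0 and equal to the
classical |P|√((σ_I/I)² + (σ_T/T)²) otherwise. CIs are never clipped to
[0, 1]. For all mediators jointly the difference method P = (T − D)/T is
used, with D the exposure's direct MVMR coefficient; a product
decomposition across several correlated mediators is deliberately out of
scope.

**One-sample MR.** Binary outcomes use the ratio of the reduced-form
logistic coefficient (outcome on allele score) to the first-stage linear
coefficient (exposure on score), SE = reduced-form SE / |first stage|;
continuous outcomes use two-stage least squares. The multivariable score
estimator solves c = Bθ, where c are reduced-form coefficients on all
scores and B[s,j] the first-stage coefficient of score s on exposure j;
reduced-form covariance is propagated through B⁻¹ (first-stage noise is
second order for strong scores). Split-sample weighting — score weights
estimated on one random half, applied to the other — avoids overlap
between weight estimation and effect estimation.

**Observational arm.** Logistic (or linear-probability, for the
risk-difference replication) regression with confounder adjustment;
product and difference constructions as above; uncertainty by
nonparametric bootstrap of individuals (percentile CIs, seed mandatory),
with a fast delta alternative. Bootstrap loops use a compact Newton
logistic solver; its agreement with statsmodels is tested.

## Harmonisation and clumping

Outcome associations are aligned to the exposure's effect allele: direct
match, allele swap (negate beta, complement the frequency), or strand
flip via base complements. Palindromic (A/T, G/C) pairs cannot be
resolved by allele labels; the default policy orients them by which side
of 0.5 the two studies' effect-allele frequencies fall on and drops SNPs
whose minor-allele frequency is within 0.08 of 0.5 (`drop_ambiguous`,
window configurable), with `infer_by_eaf` and trust-the-labels `keep`
variants. Missing frequencies drop the SNP — fail safe.

Clumping is the standard greedy procedure: visit SNPs by ascending
p-value (ties broken by larger |beta/se|, then snp_id — determinism is
asserted), keep the best, discard same-chromosome SNPs within the window
whose r² with it exceeds the threshold. Both published regimes (r² < 0.1
pairwise; r² < 0.001 within 10 000 kb) are reachable through parameters.
Positions are 1-based; distances compare |Δbp| within a chromosome.

## The synthetic study

`SynthConfig` describes one study; `simulate_cohort` draws it:

* Dosages G ~ Binomial(2, maf), maf ~ U(0.05, 0.45), independent SNPs
  (no LD — clumping is exercised on constructed LD matrices instead).
  Four disjoint panels of `m_instruments` SNPs (default 100) instrument
  education and the three mediators.
* Education: E = Σα_k(G_k − 2maf_k) + γ_u·U + ε, unit variance, with the
  panel explaining `instrument_r2` = 0.12 of the variance — the order
  reported for the large schooling GWAS. Mediator panels explain 0.06
  (BMI), 0.05 (SBP), 0.04 (smoking), the order of magnitude of the cited
  risk-factor GWAS instrument sets.
* Latent mediators: M* = θ·E + own panel + δ_u·U + ε, unit variance.
  Defaults θ = −0.22, −0.15, −0.32 per SD of education — the reported
  two-sample estimates for BMI, SBP and smoking.
* Observed mediators add classical noise with variance 1/ρ − 1
  (reliability ρ; defaults 0.95 for BMI, 0.6 for SBP and smoking,
  reflecting that BMI is measured well and the other two poorly).
* Outcome: Y ~ Bernoulli(logistic(logit(π₀) + β_d·E + Σβ_i·M*_i + φ_u·U)),
  baseline probability π₀ = 0.05. β_i are solved from the anchors so the
  true proportions mediated are 0.18, 0.21 and 0.34 and the true total is
  ln 0.63 per SD; β_d takes the remainder. Confounder loadings
  (γ_u, δ_u, φ_u) = (0.3, 0.15, 0.4) make the observational total biased
  toward the null, as observed empirically.
* Truth is computed in closed form on the linear-predictor scale, where
  total = direct + Σ indirect holds exactly; consequently the combined
  proportion is Σ P_i = 0.73. (Published analyses report a much lower
  combined figure than the sum of single-mediator figures; that reflects
  inter-mediator pathways — e.g. adiposity raising blood pressure — which
  this generator intentionally omits, keeping every estimand closed-form.)
* An `architecture_seed` separates the population (mafs, effects, allele
  labels) from the sample draw, so the two-sample pipeline can analyse
  genuinely independent exposure-side and outcome-side cohorts from one
  population. A pleiotropy knob adds direct SNP→outcome effects to a
  fraction of education SNPs for exercising Egger and the weighted median.

Per-SNP scans: continuous traits use vectorised simple regression (moment
form; single precision for large matrices, double below ~2M cells where
tests require exact agreement with per-SNP OLS). The binary outcome scan
exploits that integer dosages take three values, so per-SNP logistic
regression reduces exactly to case/control counts per genotype class;
Newton–Raphson then runs on a 3×m array and matches a conventional
logistic fit to ~1e-10. Covariate-adjusted binary scans fall back to
per-SNP fits.

What passing recovery tests show — and what they do not. The generator
reproduces the analysis' assumed causal structure, confounding,
measurement error and realistic instrument strengths; it omits LD,
population stratification, assortative mating, selection into the cohort,
inter-mediator effects and exposure measurement error. Recovery therefore
validates the estimators and their composition, not robustness to those
omitted features.

Known approximation: per-SNP logistic effects are *marginal* log odds and
are attenuated relative to the conditional generator coefficients by
non-collapsibility (about 8–10% at the default predictor variance). The
attenuation is common to numerator and denominator of every proportion,
which is why proportions recover cleanly while the recovered total OR sits
near 0.66 rather than 0.63.

## The attenuation experiment

The central methodological claim — classical measurement error in a
mediator attenuates the observational proportion mediated but not the MR
one — is tested in isolation: reliability 0.6 on all mediators,
confounder loadings zero, 200 replicates at n = 20 000 with 50 SNPs per
panel (sizes chosen to give clear separation at desk scale). The
observational proportions land near 0.6 × truth, the two-sample MR
proportions near truth. With the confounder on, the observational
proportions are additionally distorted through the attenuated total
(denominator), entangling two biases; the isolated design tests the
mechanism itself.

## Problem sizes used in validation

Estimator exactness runs on randomised small instances against
independent normal-equation/interpolation oracles (1e-10 relative).
Parameter recovery averages 50 replicates at the default n = 100 000 and
100 SNPs per panel: two-sample means within ±0.04 of the true
proportions, one-sample within ±0.06. The acceptance script averages 10
replicates of the same conditions. All randomness flows from explicit
seeds; every stochastic path (simulation, weighted-median bootstrap,
observational bootstrap) is bit-reproducible under a fixed seed.

## Other design choices

* ISCED-style qualification → schooling-years table (degree 20, NVQ/HND
  19, professional 15, A-level 13, O-level/CSE 10, none 7) is
  configurable; unknown categories raise rather than default.
* Antihypertensive use adds 10 mm Hg to measured SBP.
* Rescaling per-unit to per-SD betas multiplies beta and SE by the SD
  (education 3.6 years, BMI 4.69, SBP 18.68 mm Hg as reference values);
  a unit flag records the state and warns on repeat rescaling rather than
  forbidding it (inverting a scaling is legitimate).
* Rendering rounds odds ratios to 2 decimals and proportions to whole
  percents; machine-readable outputs keep full precision, and every table
  carries package version, config hash and seed.

## Limitations

Proxy-SNP lookup, LD estimation from reference panels, Steiger filtering,
MR-PRESSO, mode-based estimators, heterogeneity statistics beyond the
overdispersion scale, survival outcomes and four-way effect
decompositions are out of scope. Delta-method SEs assume independence of
the paired estimates (a/b, T/D, indirect/total); where sources overlap
substantially the bootstrap paths are the safer choice.
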