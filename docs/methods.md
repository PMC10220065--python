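# Methods

This note records the models behind each module, the assumptions they make,
the defaults and why, and what the synthetic data do and do not establish.

## Summary-statistics core

A `VariantRecord` is one per-variant association result in one stratum
(never-smokers, ever-smokers, or combined): effect/other allele,
effect-allele frequency (EAF), per-allele log odds ratio β with standard
error, z = β/se, two-sided p, and case/control counts. Published tables
often print `OR (95% CI)` instead of an SE; these cells are inverted with
se = (ln U − ln L) / (2·z₍(1+level)/2₎), i.e. assuming a Wald interval on the
log-odds scale — the universal GWAS convention. The normal quantile
1.959964 is used for 95% intervals.

Two numerical choices matter in practice:

* **p-values in log space.** p = 2Φ(−|z|) is evaluated through the normal
  log-survival function, and log₁₀p is stored alongside p, so variants
  beyond |z| ≈ 38 (p below the smallest double, ~1e-308) remain ordered and
  reportable.
* **Supplied p-values are kept.** When a table supplies p next to a rounded
  OR/CI cell, the p printed there usually comes from the full analysis while
  the CI is rounded to two decimals; recomputing p from the rounded cell
  would be *less* accurate. The record therefore keeps a supplied p as-is
  and derives p only when absent. The z–p consistency invariant is enforced
  for derived values.

Fixed-effect meta-analysis is the standard inverse-variance form. Allele
harmonisation precedes any combination: swapped effect/other alleles negate
β and reflect EAF; A/T and C/G pairs are strand-ambiguous and are flagged
with a warning rather than silently flipped, since allele labels alone
cannot resolve the strand. Heterogeneity between two estimates (between
ancestries, or between exposure strata for one variant) uses the Wald
contrast with a normal reference — the large-sample choice; the package does
not offer a t reference because per-variant GWAS sample sizes make the
difference negligible. BH q-values are computed by the standard step-up
rule (via statsmodels), validated in the tests against a literal
implementation of the definition.

Odds ratios are rounded to two decimals only at the reporting layer (CLI
output formatting); all internal arithmetic is full precision.

## Synthetic cohorts

The generator inverts the additive logistic model a GWAS fits. Genotypes
are Binomial(2, pₜ) — HWE, independent variants (no LD; see Limitations).
Disease follows logit P(D) = αₛ + Σₜ β₍ₜ,ₛ₎ gₜ with stratum-specific
coefficient vectors, so "no interaction" is exactly β_never = β_ever.
Cases and controls are then **retrospectively sampled to exact per-cell
quotas** from the simulated population, matching case-control ascertainment;
this keeps per-cell counts exact and makes downstream statistics insensitive
to the baseline risk.

* `target_prevalence` (default 0.1) fixes the population prevalence the
  intercept is calibrated to. Only relative effects matter downstream under
  retrospective sampling, so the default trades realism for sampling
  efficiency (a rarer disease just makes case quota filling proportionally
  more expensive). It is configurable down to rare-disease values; the
  quantile-OR validation uses 0.01.
* αₛ is calibrated by bisection on the simulated population prevalence
  (tolerance 1e-3) over a fixed-seed calibration sample, exactly (logit of
  the target) when all effects are zero. The calibration is a deterministic
  function of (frequencies, effects, target) and is cached.
* Quota filling is chunked with a budget; an unattainable quota raises a
  `SimulationBudgetError` rather than looping forever.

`summarize_cohort` emits, per variant and stratum: pooled EAF, genotypic
sample variances among cases and among controls (denominator n−1 — the
unbiased choice; recorded in the output metadata since the interaction
weight definition does not pin it down), the two-sample mean-difference
z-score, and single-variant logistic Wald statistics (statsmodels `Logit`).
Both z definitions are emitted deliberately: the interaction test's algebra
is exact for the mean-difference form and approximate for the logistic form.
Variants monomorphic within a stratum get NaN statistics, a warning, and an
explicit flag; downstream tests refuse them unless told to drop them.

## PRS × stratum interaction test

The target quantity is Δₛ, the case–control difference in mean PRS within
stratum s, and the statistic is Z = (Δ₁ − Δ₀)/√(var Δ₁ + var Δ₀) with
var Δₛ = Σₜ βₜ²((σₜˢ⁺)²/nˢ⁺ + (σₜˢ⁻)²/nˢ⁻) under variant independence.
Rewriting Δₛ as a sum over variants shows Z = Σₜ(wₜ¹zₜ¹ − wₜ⁰zₜ⁰) when zₜˢ
is the genotype mean-difference z-score — the summary and individual forms
are then *identities* of each other, which the tests verify to 1e-8 (observed
agreement: ~1e-14). Real summary files carry logistic Wald z-scores
instead; for small per-variant effects the two are asymptotically equal, and
the summary test with logistic z agrees with the oracle to |ΔZ| < 0.15 at
2000 subjects per cell in the test suite. The default `z_source` is
therefore `"logistic"` (what users actually have), with `"meandiff"` as the
exactness option.

Genotypic variances: `"observed"` uses the sample variances; `"hwe"`
substitutes 2p(1−p) from the pooled per-stratum EAF — the only option when
consuming summary files, and the CLI default for that reason. Variant-
specific sample sizes are supported (the two strata may mix data sources of
different depth). SNPs present in only one stratum are an error by default
to avoid silent bias. Z is invariant to positive rescaling of the weight
vector and to variant order; the reported p is two-sided, with the
direction of any interaction carried by the sign of Z (negative = stronger
association in the never stratum under the package's stratum ordering).

Calibration evidence (acceptance suite): over 2000 null cohorts (25
variants, 1000 subjects per cell, shared nonzero effects) the rejection
rate at α = 0.05 falls within [0.040, 0.060] and the empirical variance of
Z within [0.9, 1.1].

## PRS quantile odds ratios

Empirical mode: bin cut-points are quantiles of the **control** score
distribution (controls approximate the population under the rare-disease
assumption; the choice is recorded in the output), ORs and Wald CIs come
from the 2×2 table of each bin against the middle bin, and zero cells raise
an error unless the Haldane–Anscombe 0.5 correction is enabled. The middle
bin is the reference because it represents the average risk of the
population; K must be odd so that bin exists.

Analytic mode: with S ~ N(μ, σ²) among controls (μ = Σ2pβ, σ² = Σ2p(1−p)β²
under HWE/independence) and disease log-odds linear in S with unit loading,
the OR of bin (a,b) versus the reference is the ratio of truncated-normal
exponential moments E[e^S | a<S<b] =
e^{μ+σ²/2}·[Φ((b−μ)/σ−σ) − Φ((a−μ)/σ−σ)]/[Φ((b−μ)/σ) − Φ((a−μ)/σ)].
This is a rare-disease approximation (control distribution ≈ population).
Validation compares it with the empirical mode on a 200,000-subject
case-control cohort drawn at prevalence 0.01 (50k cases + 50k controls per
stratum): odds ratios are invariant to outcome-dependent sampling, so the
retrospective design provides ~20,000 cases per bin and per-bin Monte-Carlo
noise of ~1.5%, making the 3% agreement bound a meaningful two-sigma check.
(A prospective 200k population at that prevalence would hold only ~2000
cases and ~7% per-bin noise — too coarse to validate anything.)

## Familial relative risk

λₜ = (pOR² + 1−p)/(pOR + 1−p)² per variant; fraction explained
Σ ln λₜ / ln λ₀ under multiplicative independence across variants. λ₀ is an
external epidemiological estimate, so it is a parameter with default 1.84
(a published first-degree-relative estimate for lung adenocarcinoma).
Inputs on the protective-allele orientation are flipped to the risk allele
(p→1−p, OR→1/OR) for display; the identity λ(p,OR) = λ(1−p,1/OR) makes the
fraction invariant to the flip. The implementation is cross-checked against
the algebraically equivalent form λ−1 = p(1−p)(OR−1)²/(pOR+1−p)² to 1e-12.

## Architecture projection

Effects live on the standardized-genotype scale (the mixture is defined
after normalizing allele frequencies), which makes the estimation SE
frequency-free: se = √(1/n_cases + 1/n_controls).

* **Expected discoveries.** Marginally β̂ ~ N(0, σᵢ²+se²) within component
  i, giving the closed form M·[πp₁·2Φ(−c·se/√(σ₁²+se²)) +
  πp₂·2Φ(−c·se/√(σ₂²+se²)) + (1−π)α], c the two-sided critical value.
  Verified against brute-force simulation within 3 MC SE on a 3×3 grid of
  (sample size, polygenicity).
* **Expected AUC.** Per Monte-Carlo replicate the true effects and their
  estimates are drawn, SNP weights formed (hard threshold at genome-wide
  significance, or posterior-mean shrinkage E[β|β̂] under the mixture prior
  — the Bayes weights, which dominate thresholding in every tested design),
  and the replicate AUC evaluated as Φ(Σwβ/√(2Σw²)). This is the
  normal-PRS, rare-disease approximation: cases' score distribution shifts
  by Σwβ/σ_S standard deviations, controls approximate the population, and
  both are normal by the CLT over many independent variants. The convention
  AUC = 0.5 applies when no variant is selected. With oracle weights w = β
  the formula collapses to Φ(√(Σβ²)/2^½), which the tests use as a
  closed-form target and as a per-replicate upper bound (Cauchy–Schwarz).
* **Parameter uncertainty.** Parameter sets are resampled from a
  multivariate normal around the fitted Γ = (π, p₁, p₂, σ₁², σ₂²) with its
  covariance; since p₂ = 1−p₁ is determined, the p₂ coordinate of a draw is
  replaced by the constraint. Draws violating the parameter space are
  rejected and redrawn (clipping would pile mass on the boundary); if >90%
  of draws are invalid the covariance is declared inconsistent. The spread
  of the per-draw AUCs gives the SE and percentile CI.

Fitting the mixture to real summary statistics (an LD-aware composite
likelihood) is intentionally out of scope — it is the province of the
dedicated architecture-estimation tools; here fitted parameters are inputs,
and M (candidate variants genome-wide) must be supplied.

## Problem sizes and determinism

All stochastic routines take explicit seeds and are bit-reproducible given
(seed, replicates, M). The validation suite runs at sizes chosen to give
each check real statistical teeth while staying quick on one CPU: 2000 null
cohorts for test calibration (binomial 95% band ±0.010 around 0.05), a
200k-subject cohort for the quantile-OR comparison, M = 1e5 with 30
replicates for the discovery-projection cross-check, and 2000 logistic fits
for the null-uniformity check of the per-variant regression p-values.

## Limitations

* Variants are simulated and analysed as independent; none of the methods
  model LD. Real PRS panels are LD-pruned to approximate this, but residual
  correlation would inflate the interaction-test variance and bias the
  quantile-OR moments — passing the synthetic checks does not speak to that.
* The logistic-z route of the interaction test is asymptotic; at very small
  per-cell counts or rare variants the meandiff/logistic gap grows.
* Analytic quantile ORs and the projection AUC share the rare-disease,
  normal-score approximations; both degrade for very common diseases or
  very sparse panels (few variants → non-normal scores).
* The synthetic cohorts have no covariates, no genotyping error and no
  population structure; the generator validates the statistics, not the
  robustness of a full GWAS pipeline.
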