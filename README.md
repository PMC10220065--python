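# strataprs

Statistical toolkit for **stratified case-control GWAS summary statistics**,
built around the analysis pipeline of a two-stage lung-adenocarcinoma GWAS in
East Asian populations, where over half of cases arise in never-smokers and
the key questions are how genetic risk differs by smoking stratum and how far
larger studies can push polygenic prediction.

It is aimed at statistical geneticists who have per-variant summary tables
(log-ORs, SEs, frequencies, counts per exposure stratum) rather than
individual genotypes, and provides:

* **Summary-statistics core** — validated per-variant records with allele
  harmonisation, conversion of published `OR (95% CI)` cells back to
  (log-OR, SE), inverse-variance fixed-effect meta-analysis
  (β̂ = Σwᵢβᵢ/Σwᵢ, w = 1/se², se = (Σw)^−½), Wald heterogeneity tests
  z = (β₁−β₂)/√(se₁²+se₂²), and Benjamini–Hochberg q-values.
* **PRS × stratum interaction test from summary statistics.** For a PRS with
  weights βₜ, the interaction statistic contrasts the case–control difference
  in mean PRS between strata and decomposes (independent variants) into
  Z = Σₜ (wₜ¹zₜ¹ − wₜ⁰zₜ⁰), with
  wₜˢ = βₜ√((σₜˢ⁺)²/nˢ⁺ + (σₜˢ⁻)²/nˢ⁻) normalised so var(Z) = 1 under the
  null; zₜˢ are per-variant association z-scores and (σₜˢ±)² genotypic
  variances in cases/controls. An individual-level oracle form is included
  and is algebraically identical when mean-difference z-scores are supplied.
* **PRS modelling** — subject scoring, population moments under HWE,
  quantile-bin odds ratios versus the middle bin, both empirical (2×2
  tables, control-derived cut-points) and in closed form via truncated-normal
  exponential moments under the rare-disease approximation.
* **Familial risk decomposition** — per-variant
  λₜ = (pₜORₜ² + 1−pₜ)/(pₜORₜ + 1−pₜ)² and the fraction of familial risk
  explained Σₜ ln λₜ / ln λ₀ (λ₀ defaults to 1.84).
* **Architecture projection** — given a three-component effect-size mixture
  βₘ ~ πp₁N(0,σ₁²) + πp₂N(0,σ₂²) + (1−π)δ₀ on the standardized-genotype
  scale, the expected number of genome-wide-significant discoveries (closed
  form) and the expected PRS AUC = Φ(Σwβ/√(2Σw²)) for a training GWAS of any
  size, with threshold or posterior-mean SNP weighting and resampling-based
  parameter uncertainty.
* **Synthetic cohort generator** — stratified case-control cohorts drawn
  retrospectively from a logistic population model under HWE, so every
  stage above can be exercised and calibrated without controlled-access data.

## Worked example

```python
import numpy as np
import strataprs as sp

# 1. Two-stage meta-analysis from published OR (95% CI) cells
disc = sp.ci_to_logse(0.89, 0.86, 0.93)   # discovery
rep  = sp.ci_to_logse(0.91, 0.88, 0.94)   # replication
meta = sp.fixed_effect_meta([disc, rep])
print(f"combined OR = {meta.odds_ratio:.3f}  (log-OR {meta.beta:+.4f} "
      f"+/- {meta.se:.4f}, p = {meta.p:.2e})")

# 2. Simulate a stratified cohort in which the PRS effects are 50% larger
#    in never-smokers, then test the interaction from summary statistics
rng = np.random.default_rng(0)
eafs = rng.uniform(0.1, 0.9, 25)
beta = rng.normal(0.0, 0.15, 25)
cfg = sp.CohortConfig(
    M=25, eafs=eafs, beta_never=1.5 * beta, beta_ever=beta,
    n_cases_never=3000, n_controls_never=3000,
    n_cases_ever=3000, n_controls_ever=3000, seed=1,
)
cohort = sp.simulate_cohort(cfg)
summary = sp.summarize_cohort(cohort, include_logistic=False)
weights = sp.PrsWeightSet(snp_ids=list(cohort.snp_ids),
                          effect_alleles=list(cohort.effect_alleles),
                          weights=beta)
res = sp.interaction_test_summary(summary.stats, weights, z_source="meandiff")
print(f"interaction Z = {res.Z:+.2f}, p = {res.p:.2e}")

# 3. Familial relative risk explained by the panel (risk-allele scale)
variants = [sp.FamilialVariant(p=float(p), odds_ratio=float(np.exp(abs(b))))
            for p, b in zip(eafs, beta)]
frr = sp.frr_fraction(variants, lambda0=1.84)
print(f"fraction of familial risk explained = {100 * frr.fraction:.1f}%")

# 4. Project the PRS AUC of a future 70k/70k GWAS under a polygenic architecture
arch = sp.GeneticArchitecture(M=1_000_000, pi=0.00228, p1=0.1, p2=0.9,
                              sigma1_sq=5e-4, sigma2_sq=5e-5)
design = sp.StudyDesign(n_cases=70_000, n_controls=70_000)
auc, mc_se = sp.expected_auc(arch, design, weighting="posterior_mean",
                             mc_reps=200, seed=0)
print(f"expected discoveries = {sp.expected_discoveries(arch, design):.0f}, "
      f"projected AUC = {100 * auc:.1f}% (MC se {100 * mc_se:.2f})")
```

Output:

```
combined OR = 0.902  (log-OR -0.1035 +/- 0.0129, p = 8.42e-16)
interaction Z = -5.44, p = 5.18e-08
fraction of familial risk explained = 17.0%
expected discoveries = 49, projected AUC = 58.5% (MC se 0.04)
```

Reading the numbers: the discovery and replication odds ratios combine to
0.90 with a much tighter interval than either stage alone; the negative
interaction Z says the PRS–disease association is stronger in the
never-smoker stratum (the generative truth here, by construction); the
familial-risk fraction expresses the panel's cumulative log-λ relative to a
first-degree familial risk of 1.84; and under the assumed mixture
architecture a 70k/70k study is projected to yield ~49 genome-wide-significant
variants and a PRS with 58.5% AUC.

A `strataprs` command-line entry point wraps the same functions
(`meta`, `het`, `interact`, `prs-quintiles`, `frr`, `project`); run
`strataprs --help` for the formats.

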