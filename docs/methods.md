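# Methods

## Problem setting

Two geographically adjacent populations show a persistent gap in
coronary-artery-disease (CAD) prevalence (England 7.68%, Scotland
8.98% among biobank participants — a 16.9% relative difference). The
package implements the analysis chain used to ask whether that gap is
visible in (a) the common-variant genetic risk burden, summarised by
additive genetic risk scores over a panel of GWAS lead SNPs, or
(b) traditional clinical risk, summarised by a sex-stratified Cox
10-year risk score — and to localise where the two gene pools *do*
differ, via a per-SNP risk-allele-frequency scan.

## Genetic risk scores

The additive polygenic model scores individual *i* as
`GRS_i = Σ_k b_k X_ik` with `X_ik ∈ {0,1,2}` the risk-allele dosage at
SNP *k*. With all `b_k = 1` this is the raw risk-allele count (uGRS);
with `b_k = ln OR_k` the log-odds-weighted score (wGRS). Natural log is
used: it is the logistic-regression convention from which published
odds ratios come.

Missing genotypes are imputed by their Hardy–Weinberg expectation,
`2 × RAF`, where RAF is the risk-allele frequency among non-missing
genotypes. Imputation frequency is computed over the pooled analysis
cohort by default (a per-population option exists); imputing a column
at its own frequency leaves the column mean unchanged, an identity the
tests verify to 1e−12. Dosage orientation is handled at ingestion: a
VCF record contributes `ALT count` when the risk allele is ALT and
`2 − ALT count` when it is REF. Alleles must match literally — no
strand flipping is attempted, and palindromic (A/T, C/G) pairs are
matched literally with a warning, since orientation for them cannot be
proven from allele letters. Raw dosages are stored as float32 (exact
for {0,1,2} and NaN); imputation and scoring compute in float64.

## Clinical 10-year risk

The Cox-survival score is `risk% = (1 − S₀^exp(L − L̄)) × 100`, with L
the sex-specific linear predictor, S₀ the baseline 10-year survival and
L̄ the derivation-cohort mean linear predictor. Coefficients are data,
not code: the engine evaluates any declarative spec (variable,
ln/identity transform, optional boolean guard, coefficient; per-sex
blocks with S₀ and L̄). Systolic blood pressure enters through exactly
one of two treatment-guarded terms; smoking and diabetes are unguarded
binaries. The shipped `frs_lipids` and `frs_bmi` files carry the
published sex-stratified general-CVD Cox coefficients (lipid-based and
office-based variants). The engine clips the exponent at 700 so extreme
predictors saturate at 0/100 instead of overflowing.

## Between-population statistics

* Prevalence and categorical covariates: Pearson chi-squared on the
  2×2 table, **without** continuity correction — at biobank sample
  sizes the correction is negligible, and the uncorrected statistic
  equals the squared pooled two-proportion z (an identity the tests
  check numerically). A correction flag exists in the run config.
* Approximately normal scores (uGRS, wGRS): Welch's unequal-variance t.
* Skewed clinical risks: two-sided Mann–Whitney, normal approximation
  with tie correction (cohort sizes are far beyond exact-method range).
* Distributions: two-sample Kolmogorov–Smirnov, asymptotic p.

The frequency scan builds, per SNP, the allele-count 2×2 (risk vs
other allele; chromosomes = 2 × non-missing samples per population) —
allele counting rather than genotype-table testing, the standard
realisation of a frequency comparison. The m raw p-values are
Bonferroni-adjusted (`p_adj = min(1, m·p)`); scan rows default to the
stringent adjusted `p < 0.001` threshold, with the conventional 0.05
available via `alpha_adj`. Variants monomorphic in both populations
yield p = 1 and direction `none` rather than an error. The scan's
chi-squared is computed vectorised in closed form and is cross-checked
against the scalar scipy route in the tests.

## Synthetic cohort generator

The generator defines the study conditions; every downstream claim is
tested against its ground truth.

* **Frequency table**: baseline risk-allele frequencies uniform on
  (0.1, 0.9); a chosen number of variants (37/35 of 163 by default) are
  offset in population B by ±delta. Delta may be a scalar or a range
  sampled per variant; the default range (0.003, 0.033) mirrors the
  observed 0.3–3.3 percentage-point spread, while the planted-recovery
  analyses use the scalar 0.02. An offset that would leave (0,1) is an
  error, not a clamp.
* **Genotypes**: Hardy–Weinberg, dosage ~ Binomial(2, p) per sample,
  independent across loci (no linkage disequilibrium) and independent
  of covariates; calls masked missing at rate 0.002 by default,
  emulating post-QC biobank missingness.
* **Phenotypes**: truncated normals at the published per-country
  means/SDs (age 56.7±8.1 / 56.6±8.0, BMI, SBP, lipids) within wide
  physiologic bounds (age 30–90, BMI 12–70, SBP 60–260, …) chosen so
  truncation perturbs means by < 0.05 of a unit; binaries Bernoulli at
  the published rates (smoking 10.2% / 12.8%, diabetes 7.8% / 6.0%,
  antihypertensives 22.9% / 23.7%, female 53.4% / 54.5%).
* **Lipid units**: the published characteristics table labels HDL 26.2
  and total cholesterol 102.8 as mg/dL — implausible in those units.
  The default profiles reproduce the printed numbers verbatim so the
  marginal-recovery checks are faithful to the source; `ENGLAND_MGDL` /
  `SCOTLAND_MGDL` profiles with realistic mg/dL lipids (TC 220±42,
  HDL 55±14) ship for Framingham-scoring examples, since those
  coefficients expect mg/dL.
* **Disease**: `P(CAD) = logistic(α + β_g (wGRS − mean) + Σ β_j x_j)`.
  Defaults: β_g = 0.4 per wGRS unit (≈0.2 per wGRS SD, a modest
  common-variant effect) and modest clinical log-odds (male 0.65, age
  0.055/yr, smoking 0.55, diabetes 0.85, SBP 0.010/mmHg, BMI
  0.03/unit). α is calibrated by bisection so the *expected* prevalence
  — the mean fitted probability, free of sampling noise — hits the
  target (7.68% / 8.98%) to 1e−4. A logistic refit recovers β_g within
  3 SE, verified over 20 replicates at n = 50,000.
* **Odds ratios**: uniform on (1.03, 1.12) — the panel's published
  floor of 1.03, capped where lead-SNP effects for common complex
  disease typically lie; this puts the simulated wGRS mean near the
  reported ~10.6 for a 163-SNP panel.
* **Reproducibility**: all draws come from per-stage children of one
  seed; generation is bit-for-bit reproducible from (config, seed).

What the generator does **not** emulate: linkage disequilibrium and
correlated loci, relatedness/kinship, genotype–covariate correlation
(population stratification), age-dependent incidence, genotyping batch
effects, and unit heterogeneity in real biobank fields. Passing tests
therefore demonstrate correctness of the *methods* under idealised
sampling, not robustness to those real-data complications.

## Problem sizes and numerical choices

Routine tests run at desk scale (hundreds to tens of thousands of
samples); the direction-split recovery analyses run at the full
317,889 / 31,963 sizes (20 replicates), and familywise-error
calibration uses 500 replicate null scans at the default 30,000 / 3,000
scale — sizes chosen to make each claim statistically decisive while a
full suite completes in minutes on one core. Pipeline outputs round
floats to 6 significant digits for byte-stable re-runs; p-values in
reports print as `< 0.001` below that bound and with 4 significant
digits otherwise. The score engine is verified against a naive
double-loop oracle to 1e−10 on 200 random matrices.

## Scope and limitations

* No genome-wide (millions-of-variants) score with LD-aware shrinkage:
  that requires external trained weight sets and an LD reference panel.
* No QRISK3-style 22-variable algorithm; the clinical engine covers
  log-linear Cox scores with boolean guards, not fractional-polynomial
  interactions.
* Real-genotype ingestion handles biallelic SNVs with hard GT calls
  only (no imputed dosages, no BGEN/PLINK binary formats); half-calls
  are treated as missing with a warning.
* The per-SNP scan tests marginal frequencies; it does not correct for
  population stratification or relatedness, which the generator does
  not produce but real cohorts do.
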