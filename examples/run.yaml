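# Example configuration for `cadpop run-all --config examples/run.yaml --out results/`
# Exactly one of `simulate:` or `inputs:` may be present.
seed: 17
simulate:
  profile_a: England        # built-in profiles: England, Scotland, England_mgdl, Scotland_mgdl
  profile_b: Scotland
  n_a: 30000                # omit (with full_scale: true) for 317,889 / 31,963
  n_b: 3000
  n_variants: 163
  n_higher_a: 37            # planted higher-frequency variants per population
  n_higher_b: 35
  delta: [0.003, 0.033]     # per-variant planted offset range (frequency units)
  missing_rate: 0.002
imputation_scope: pooled    # or per_population
clinical_specs: [frs_lipids, frs_bmi]
alpha: 0.05
alpha_adj: 0.001            # scan significance threshold on Bonferroni-adjusted p
# inputs:                   # real-data alternative to `simulate:`
#   weights: weights.tsv
#   vcf_a: england.vcf
#   vcf_b: scotland.vcf
#   phenotypes: phenotypes.tsv
#   population_a: England
#   population_b: Scotland
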