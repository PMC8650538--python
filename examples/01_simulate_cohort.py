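"""Simulate a two-population biobank-style cohort and inspect its marginals.

Generates 8,000 England-like and 2,000 Scotland-like participants with
163 risk SNPs (37 planted at higher frequency in England, 35 in
Scotland) and prints the phenotype marginals and disease prevalences
the generator was calibrated to.
"""

from cadpop import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n_a=8000, n_b=2000), seed=42)
phen = cohort.phenotypes

for label in ("England", "Scotland"):
    sub = phen[phen["population"] == label]
    print(f"\n{label} (n={len(sub):,})")
    print(f"  mean age  {sub['age'].mean():5.1f}   mean SBP {sub['sbp'].mean():6.1f}")
    print(f"  smokers   {100 * sub['smoker'].mean():5.1f}%  diabetics {100 * sub['diabetic'].mean():4.1f}%")
    print(f"  CAD prevalence {100 * sub['cad'].mean():5.2f}%")

truth = cohort.freq_table.to_frame()
print("\nPlanted frequency differences:")
print(truth["planted_direction"].value_counts().to_string())
print("\nThe prevalences approach the 7.68% / 8.98% calibration targets as n grows;")
print("the planted split (37 higher in England, 35 in Scotland) is the scan's ground truth.")
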