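"""Per-SNP risk-allele-frequency scan with Bonferroni correction.

Plants known frequency differences between two populations (37 SNPs
higher in A, 35 higher in B, 2 percentage points each), simulates
genotypes at biobank scale, and checks that the scan recovers the
planted split.
"""

from cadpop import af_scan, make_frequency_table, summarize_scan
from cadpop.popcompare import dumbbell_table
from cadpop.synthetic_cohort import simulate_genotypes

freqs = make_frequency_table(163, 37, 35, 0.02, (0.1, 0.9), seed=5)
ma = simulate_genotypes(freqs.raf_a, 100_000, freqs.variant_ids, seed=6)
mb = simulate_genotypes(freqs.raf_b, 10_000, freqs.variant_ids, seed=7)

scan = af_scan(ma, mb, alpha_adj=0.001)
s = summarize_scan(scan)
print(f"variants scanned: {s['m']}")
print(f"significantly higher in A: {s['n_higher_A']}  (planted: 37)")
print(f"significantly higher in B: {s['n_higher_B']}  (planted: 35)")
print(f"no significant difference: {s['n_nonsignificant']}")
print(f"absolute frequency differences among hits: "
      f"{100 * s['min_abs_diff']:.1f} - {100 * s['max_abs_diff']:.1f} pp")

top = dumbbell_table(scan).head(5)
print("\nlargest differences (dumbbell-table rows):")
print(top[["rsid", "raf_a", "raf_b", "diff", "p_adj"]].round(4).to_string(index=False))
print("\nAt these sample sizes a 2 pp frequency difference gives a per-SNP z around 9,")
print("so nearly every planted variant survives Bonferroni correction over 163 tests.")
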