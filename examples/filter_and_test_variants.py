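"""Filter a longitudinal variant call set and test mutation accumulation.

Generates a synthetic WGS call set for a seed culture expanded under slow
(1% FBS) and fast (5% FBS) serum conditions, applies the exclusion filters
in both baseline modes, counts novel SNVs per sample, and runs the two-way
ANOVA (serum group x time point) plus the VAF-distribution comparison.
"""

from clonaldyn import synthetic_data as sd
from clonaldyn import variant_pipeline as vp

records, sheet, truth = sd.gen_variants(seed=7)
print(f"call set: {len(records)} variants, "
      f"{len(sheet.culture_samples)} culture samples + 1 seed sample")

for mode in ("strict", "relaxed"):
    kept = vp.filter_variants(records, vp.FilterConfig(mode=mode), sheet)
    print(f"  {mode:7s} filter: {len(kept)} variants retained")

kept = vp.filter_variants(records, vp.FilterConfig(mode="strict"), sheet)
counts = vp.count_novel_snvs(kept, sheet)
print("\nnovel SNVs per (group, timepoint):")
print(counts.groupby(["fbs_group", "timepoint"])["count"]
      .agg(["mean", "var"]).round(2))

res = vp.group_anova(counts)
print(f"\ntwo-way ANOVA, serum-group effect: F = {res.f_group:.2f}, "
      f"p = {res.p_group:.4f}")
print(f"  between-group SS = {res.ss_group:.1f}, within SS = {res.ss_within:.1f}")

relaxed = vp.filter_variants(records, vp.FilterConfig(mode="relaxed"), sheet)
chrom = vp.chromosomewise_analysis(relaxed, sheet, min_variants=4)
print(f"\nchromosome-wise ANOVA (>= 4 variants): {len(chrom)} chromosomes retained")

summary, p_vaf = vp.vaf_distribution_summary(relaxed, sheet)
print("\nVAF distributions per (group, timepoint):")
print(summary.round(3).to_string(index=False))
print(f"between-group VAF comparison (rank test): p = {p_vaf:.3f}")
print()
print("A significant group effect on counts with an unchanged VAF")
print("distribution means faster growth accumulated more mutations without")
print("reshaping the fitness landscape (no clonal sweep).")
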