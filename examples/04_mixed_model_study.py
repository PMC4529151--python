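"""Study-level statistics on a simulated cohort.

Generates a study table (9 subjects, 16 eyes, 6 peripapillary regions,
with eyes nested in subjects) whose ICD is linked to RNFL thickness
with slope -0.065 μm/μm, then runs the three analyses: the ICD~RNFL
mixed model, the arcuate-vs-other contrast, and a technique comparison
with a nasal-only offset.
"""

import warnings

import rpcsvoct as r

warnings.filterwarnings("ignore")

table = r.generate_study_table(n_subjects=9, rnfl_slope=-0.065, seed=11,
                               techniques=("svOCT", "histology"),
                               technique_icd_offsets={"N": 4.0})
print(f"{len(table)} records: {table['subject'].nunique()} subjects, "
      f"{table.groupby('subject')['eye'].nunique().sum()} eyes, "
      f"{table['region'].nunique()} regions, 2 techniques\n")

fit = r.fit_icd_rnfl(table)
print(f"ICD ~ RNFL slope: {fit.slope:.4f} ± {fit.slope_se:.4f} μm/μm "
      f"(P = {fit.slope_p:.4f}); generating value -0.065")
print("  -> thicker nerve fibre layer, denser capillary bed "
      "(smaller ICD)\n")

est, p = r.compare_arcuate(table)
print(f"arcuate (ST+IT) vs other regions, log-ICD contrast: {est:+.3f} "
      f"(P = {p:.2g})")
print("  -> negative: the arcuate bundles carry the densest beds\n")

tech = r.compare_techniques(table)
print("svOCT vs histology (log-ICD), per region:")
for _, row in tech.iterrows():
    flag = " *" if row["p"] < 0.05 else ""
    print(f"  {row['region']:>6}: estimate {row['estimate']:+.3f}, "
          f"P = {row['p']:.3f}{flag}")
print("  -> only the nasal region (given a 4 μm histology offset by "
      "construction) should be flagged\n")

ages = r.ages_ttest([28, 35, 41, 44, 50, 52, 57, 60, 33],
                    [15, 32, 39, 44, 51, 58, 63, 70, 75])
print(f"subject vs donor ages: {ages['summary']}")
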