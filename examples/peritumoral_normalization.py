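"""Compare peritumoral activity with its contralateral homologues.

For each patient, ten regions near the tumor rim are paired with their
mirror-image regions in the opposite hemisphere; activity is summarized
on both sides and their ratio cancels pre-existing regional
differences.  A paired Wilcoxon test then asks whether peritumoral
activity is systematically elevated across patients.
"""

from periglioma import (CohortConfig, cohens_d_paired, generate_cohort,
                        wilcoxon_signed_rank)
from periglioma.pipeline import analyze_subject

config = CohortConfig(n_patients=12, n_controls=0, n_regions=20,
                      sampling_rate=250.0, artifact_rate=0.0,
                      recording_duration=3 * 13.1 + 0.1, seed=11)
cohort = generate_cohort(config)

peri_offsets, contra_offsets = [], []
for _, row in cohort.subjects.iterrows():
    sid = row["subject_id"]
    summaries = analyze_subject(
        cohort.timeseries(sid), cohort.atlas,
        peritumoral=cohort.peritumoral[sid],
        tumor_hemisphere=row["tumor_hemisphere"], n_epochs=3)
    by_level = {s.level: s for s in summaries}
    peri_offsets.append(by_level["peritumoral"].offset)
    contra_offsets.append(by_level["contralateral"].offset)
    if sid == "P001":
        norm = by_level["normalized"]
        print(f"P001 normalized (peritumoral/contralateral) ratios: "
              f"power {norm.broadband_power:.3f}, offset {norm.offset:.3f},"
              f" slope {norm.slope:.3f}")

res = wilcoxon_signed_rank(peri_offsets, contra_offsets)
d = cohens_d_paired(peri_offsets, contra_offsets)
print(f"\npaired Wilcoxon on the offset, n={len(peri_offsets)} patients: "
      f"W={res.statistic:.0f}, p={res.p_value:.4f} ({res.method})")
print(f"paired effect size D={d:.2f}; D > 0 means peritumoral activity "
      "exceeds the contralateral homologues, the expected direction for "
      "tumor-adjacent cortex")
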