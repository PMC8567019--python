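"""Generate a synthetic EPIC-like cohort and inspect its ground truth.

The generator emulates a small three-group methylation study: healthy
controls, skin psoriasis and psoriatic arthritis, with some patients
sampled before and after cytokine-blocker treatment.  Planted effects
(differential probes/regions, batch shifts, activity-coupled CpGs) are
returned alongside the data so downstream stages can be scored.
"""

from methcd8 import CohortDesign, generate_cohort, generate_manifest

design = CohortDesign(n_probes=2000, seed=1)
manifest = generate_manifest(design)
matrix, sheet, truth = generate_cohort(design, manifest)

print(f"cohort: {matrix.shape[0]} probes x {matrix.shape[1]} samples")
print(sheet.frame.groupby("group")["sample_id"].count().to_string())
print(f"\npaired treated subjects: {sheet.paired_subjects()}")
print(f"planted DMPs (HC vs Pso): {len(truth.dmp_probe_ids['HC_vs_Pso'])}")
print(f"planted DMR intervals:    {truth.dmr_intervals['HC_vs_Pso']}")
print(f"activity CpGs:            {truth.activity_probe_ids}")
pasi = sheet.frame.dropna(subset=["pasi"])
print(f"\nPASI range over {len(pasi)} patient samples: "
      f"{pasi['pasi'].min():.1f} - {pasi['pasi'].max():.1f}")
print("Higher PASI = more active skin disease; the planted activity CpGs "
      "are hypomethylated in proportion to it.")
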