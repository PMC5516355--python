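"""Generate a synthetic 57/59 serum cohort and summarize its signatures.

Builds the default desk-scale cohort (duplicate runs per patient, a spiked
internal standard, seven planted class-discriminative masses) and prints the
per-class patient counts, the mean between-run correlation, and the detected
internal-standard intensity.
"""

import ladspectra as ls

config = ls.cv_scale_config(seed=1)
records = ls.generate_cohort(config)
summary = ls.cohort_summary(records, standard_mz=config.standard_mz)

print(f"records: {len(records)} ({len(summary['per_patient'])} patients x "
      f"{config.replicates_per_patient} runs)")
print(f"class counts: {summary['class_counts']}")
print(f"mean between-run Pearson r: {summary['mean_replicate_r']:.3f} "
      f"(target {config.replicate_correlation})")
print(f"internal standard intensity: {summary['standard_intensity_mean']:.2f} "
      f"+/- {summary['standard_intensity_sd']:.2f} "
      f"(drawn from {config.standard_intensity_mean} +/- "
      f"{config.standard_intensity_sd}, plus run noise)")
print()
print("The cohort mimics a two-class proteomic study: 'rapid' kidney-function")
print("decliners vs 'slow' ones, with most planted discriminative peaks higher")
print("in the slow class.  Between-run correlation near the target confirms the")
print("replicate-noise calibration.")
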