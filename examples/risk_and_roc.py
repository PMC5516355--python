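"""Risk scores, quintile risk groups and ROC from the LAD discriminant.

For each patient the discriminant is delta = p/P - n/N (the fraction of
positive patterns covering the patient minus the fraction of negative
ones); the risk score (delta + 1)/2 rescales it to [0, 1].  Patients are
then split into quintiles of ascending risk, and the score's discrimination
is summarized as the Mann-Whitney AUC.
"""

import ladspectra as ls

config = ls.planted_recovery_config(seed=1)
records = ls.generate_cohort(config)
spec = ls.BinningSpec(low=config.mz_range[0], high=config.mz_range[1] - 2.0,
                      width=2.0)
matrix, _ = ls.build_feature_matrix(records, spec,
                                    standard_mz=config.standard_mz)
fitted = ls.fit_lad_pipeline(matrix)
results = ls.predict_matrix(fitted.model, matrix)

table = ls.risk_groups(results, matrix.labels, matrix.patient_ids, g=5)
print("risk group | n  | % rapid | mean risk")
for _, row in table.table.iterrows():
    print(f"    {int(row['group'])}      | {int(row['n'])} | "
          f"{row['pct_positive']:6.2f}  |  {row['mean_risk']:.3f}")

auc = ls.roc_auc([r.risk for r in results], matrix.labels)
print(f"\nAUC {auc.auc:.3f} ({auc.method} CI {auc.ci_low:.3f}-{auc.ci_high:.3f})")
print("A well-separated cohort puts 0% rapid progressors in the lowest risk")
print("quintile and 100% in the highest; the 116 patients split 23/23/23/23/24.")
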