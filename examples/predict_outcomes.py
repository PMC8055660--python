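"""Predict post-treatment scores from fALFF features through the full chain.

Simulates a 30-subject cohort, runs QC + group ICA + fALFF extraction,
then fits the elastic-net prognostic model under nested leave-one-out
cross-validation and reports the evaluation statistics.
"""

from falff_prognosis import (
    CohortConfig,
    CohortTable,
    evaluate_predictions,
    loocv_predict,
    make_cohort,
    qc_filter,
    run_group_ica,
)
from falff_prognosis.falff import falff_features

cohort = make_cohort(CohortConfig(n_subjects=30, n_sources=5, seed=11))
retained, _ = qc_filter(cohort.scans)
decomp = run_group_ica(retained, n_components=5, seed=11)
feats = falff_features(decomp)

predictors = feats.to_frame().drop(columns="subject_id")
predictors["pre_tsm"] = cohort.pre_tsm
table = CohortTable(cohort.subject_ids, predictors, cohort.pre_tsm, cohort.post_tsm)

result = loocv_predict(table)  # tune + fit exclude each held-out subject
report = evaluate_predictions(result.predictions, result.actual, n_boot=500, seed=0)

print(f"n = {report.n}")
print(f"MAD  = {report.mad:.3f}  (95% CI {report.mad_ci95[0]:.3f}-{report.mad_ci95[1]:.3f})")
print(f"R^2  = {report.r_squared:.3f}  "
      f"(95% CI {report.r_squared_ci95[0]:.3f}-{report.r_squared_ci95[1]:.3f})")
print(f"better than chance: Wilcoxon p = {report.wilcoxon_p_vs_zero_order:.2g}")
print(f"correlation test:   p = {report.correlation_test_p:.2g}")
# A high R^2 with a small Wilcoxon p means the model recovered the planted
# linear dependence of outcome on pre-treatment score and fALFF profile.
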