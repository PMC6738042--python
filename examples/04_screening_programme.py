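"""Simulate an annual screening programme on a synthetic cohort.

Risk probabilities are mapped to positive predictive values under an assumed
disease prevalence, and each subject's latest sample before every annual
cut-off (years 4..1 before diagnosis) is classified normal / intermediate /
elevated / severe at PPV thresholds 2.5% / 5% / 30%.
"""

from ovascreen import (
    Cohort, CohortConfig, build_ppv_table, build_training_set, fit_logit,
    generate_cohort, predict_risk, roc_analysis, score_cohort,
    simulate_screening,
)

PREVALENCE = 0.004  # placeholder for an unscreened-population EOC prevalence

subjects, samples = generate_cohort(CohortConfig(rng_seed=1))
cohort = Cohort(subjects, samples, aligned=True)
scores, _, _ = score_cohort(cohort)
model = fit_logit(build_training_set(cohort, scores))

groups = {s.subject_id: s.group for s in subjects}
probs, labels = [], []
for v in scores:  # cases (both histotypes) < 2 years tDx vs all controls
    if groups[v.subject_id] == "control":
        probs.append(predict_risk(v, model)); labels.append(0)
    elif v.tdx < 2.0:
        probs.append(predict_risk(v, model)); labels.append(1)
auc, roc_rows = roc_analysis(probs, labels)
print(f"ROC of cases <2y tDx vs controls: AUC {auc:.3f} over {len(roc_rows)} thresholds")

ppv_table = build_ppv_table(roc_rows, PREVALENCE)
trajectories, summary = simulate_screening(cohort, scores, model, ppv_table)

print(f"\nfraction classified severe per screening year (prevalence {PREVALENCE}):")
print(summary.severe_fraction.pivot(index="year", columns="group", values="fraction")
      .round(2))
print("\nyear-over-year class transitions (river-plot edges), Type II cases:")
print(summary.transitions.query("group == 'type2' and count > 0").head(12).to_string(index=False))
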