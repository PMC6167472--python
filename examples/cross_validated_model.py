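"""Stepwise logistic modeling with repeated stratified cross-validation.

Simulates a cohort whose decline outcome follows a known logistic model
over one informative feature among ten candidates, then reports the
leak-free 10x10 cross-validated AUROC with its percentile CI and the
Youden-index operating point, the protocol used for every model in the
suite.
"""

from tbivitals.modeling import repeated_cv, stepwise_select
from tbivitals.synthetic import CohortGenParams, simulate_cohort

schema = [f"f{i}" for i in range(10)]
features, cohort = simulate_cohort(
    CohortGenParams(n_patients=600, nd_prevalence=0.25, true_coefficients={"f0": 1.2}, seed=11),
    schema,
)
data = features.merge(cohort, on="patient_id")
print(f"analytic AUROC of the generating score: {features.attrs['analytic_auroc']:.3f}")

fit = stepwise_select(features[schema], cohort["nd"].to_numpy())
print(f"stepwise selection on all data picks: {fit.variables}")

cv = repeated_cv(data, "nd", schema, k=10, repeats=10, seed=12)
print(f"cross-validated AUROC {cv.auroc_point:.3f} "
      f"(95% CI {cv.auroc_ci_low:.3f}-{cv.auroc_ci_high:.3f})")
print(f"Youden operating point: threshold {cv.youden_threshold:.3f}, "
      f"sens {cv.sensitivity:.2f}, spec {cv.specificity:.2f}, "
      f"PPV {cv.ppv:.2f}, NPV {cv.npv:.2f}")
print("the CV point sits below the analytic ceiling because selection and "
      "fitting are re-run inside every training fold (no leakage)")
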