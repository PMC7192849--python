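"""Test a candidate marker for state and trait prediction.

State: does the Z-scored marker level separate high-stress visits (VAS
Life Stress >= 67) from the rest (ROC AUC with one-sided rank-sum p)?
Trait: does it predict future hospitalization with stress (Cox
proportional hazards on days to first stress admission, HR oriented so
that > 1 always means increased risk)?  Evaluation is repeated in all
subjects, by gender, and by gender x diagnosis.
"""

import pandas as pd

from stressmark import SimConfig, generate_cohort
from stressmark.prediction import stratified_evaluation, testing_points

# strong subject-level heterogeneity (subject_sd) makes the trait signal
# visible: the hazard is linear in each subject's marker exposure
config = SimConfig(
    n_subjects=40, n_probesets=100, n_planted_de=5, n_planted_ap=0,
    effect_log2fc=1.2, noise_sd=0.3, subject_sd=0.8, n_severe_subjects=0,
    hosp_hazard_marker_coef=2.0, seed=19,
)
visits, eset, hosp, followup, truth = generate_cohort(config)

marker = truth.hazard_marker  # planted DE marker that also drives hazard
direction = "increased" if truth.planted_de[marker] > 0 else "decreased"
markers = pd.DataFrame({"direction": [direction]}, index=[marker])

results = stratified_evaluation(
    markers, visits, eset.values.loc[[marker]], hosp, followup,
    modes=("cross_sectional",),
)
cols = ["stratum", "outcome", "n_positive", "n_total", "auc", "auc_p",
        "hazard_ratio", "hr_p"]
print(results[results["stratum"].isin(["all", "M", "F"])][cols].round(4)
      .to_string(index=False))

for outcome in ("state_high_stress", "hosp_all_future"):
    pts = testing_points(results, outcome)
    print(f"\ntesting points for {outcome}: {pts} "
          "(8 = significant in all, 6 = by gender, 4 = by gender/diagnosis)")
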