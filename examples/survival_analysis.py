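"""Time-to-onset analysis of the synthetic trial.

Fits a Cox proportional hazards model of time to onset of major depression
on treatment (with post-hoc pruning of the concurrent-antidepressant-use
covariate when it is not predictive), and computes the restricted mean
depression-free survival time per arm over the 12-month horizon.
"""

from depcea import SyntheticTrialConfig, generate_cohort
from depcea.survival import (
    build_survival_records,
    fit_cox,
    restricted_mean_survival,
)

cohort = generate_cohort(SyntheticTrialConfig(), seed=1)
records = build_survival_records(cohort.participants,
                                 covariates=("antidepressant_use",))

cox = fit_cox(records, covariates=("antidepressant_use",))
print(f"hazard ratio (intervention vs control): {cox.hazard_ratio:.2f} "
      f"(95% CI {cox.ci_low:.2f}-{cox.ci_high:.2f}, p={cox.p_value:.2g})")
if cox.pruned:
    print(f"covariates pruned as non-predictive: {', '.join(cox.pruned)}")
print("A hazard ratio below 1 means the intervention delays onset of "
      "major depression.")

rmst = restricted_mean_survival(records)
for _, row in rmst.iterrows():
    print(f"{row['arm']:>13}: restricted mean depression-free survival "
          f"{row['mean_weeks']:.0f} weeks "
          f"(95% CI {row['ci_low']:.0f}-{row['ci_high']:.0f}) "
          f"over the 52.18-week horizon")
print("Dividing these means by 52.18 gives each arm's mean "
      "depression-free years.")
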