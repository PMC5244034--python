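# Data dictionary

## participants.csv (one row per participant)

| column | meaning |
|---|---|
| pid | participant identifier |
| arm | `intervention` or `control` |
| age | years at baseline |
| sex | `female` / `male` |
| employed | in paid employment at baseline |
| gross_daily_wage | € per working day (0 if not employed) |
| baseline_symptoms | depressive symptom score (CES-D-style) |
| symptom_z | standardized severity (generator latent; kept for audits) |
| antidepressant_use | on a stable antidepressant dose at entry |
| onset_day | day of MDD onset in [0, 365.25]; empty if censored |
| event | onset observed within follow-up |
| intervention_hours | participant time spent on the programme (h) |

## waves.csv (one row per participant × wave)

| column | meaning |
|---|---|
| wave | 0 = baseline, 1 = 6 weeks, 2 = 6 months, 3 = 12 months |
| time_years | 0, 42/365.25, 0.5, 1.0 |
| observed | wave assessment completed (monotone dropout) |
| eq5d, sf6d | utility index values (missing when unobserved) |
| gross_daily_wage | copied from the participant record for costing |
| efficiency_rating | 0–10 self-rated efficiency on presenteeism days |
| gp_visits … presenteeism_days | resource-use quantities of the 3-month recall window (waves 2 and 3 only); `*_spend` and `copayments` are € amounts, `*_hours` hours, `travel_km` km, the rest counts/days |

## participant_costs.csv

`pid`, `arm`, then one € column per cost category (annual, already
extrapolated): intervention, gp_internist, mental_health, other_specialist,
inpatient, daycare, antidepressants, private_therapist, copayments, otc,
informal_care, domestic_help, travel, absenteeism, presenteeism,
opportunity_time.

## cost_table.csv

Per category and per perspective total: `mean_intervention`,
`sd_intervention`, `mean_control`, `sd_control`, `incremental`, plus `_gbp`
conversions at £0.85/€.

## cea_table.csv

One row per analysis (`main` / `no_hospitalization`) × perspective ×
effect: `delta_cost` with `ci_cost_low/high`, `delta_effect` with
`ci_effect_low/high`, `icer` with `icer_ci_low/high`,
`icer_ci_undefined` (True when no percentile interval exists), and
`share_{ne,nw,se,sw}_pct` quadrant shares summing to 100.

## ceac_*.csv / scatter_*.csv

`wtp`, `probability` grid per variant; `delta_effect`, `delta_cost` per
bootstrap replicate.

## imputation_audit.csv

`target`, `n_observed`, `n_imputed`, `predictors` (retained, `;`-joined),
`coefficients` (`name=value;…`).

## survival_summary.csv

Per arm: `mean_weeks` (restricted mean depression-free survival),
`ci_low`, `ci_high`, `n`, `events`.
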