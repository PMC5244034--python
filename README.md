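# depcea

Trial-based cost-effectiveness and cost-utility analysis for depression
prevention trials, with a synthetic-trial generator that lets the entire
pipeline be exercised and tested without access to patient-level data.

## The problem

Indicated prevention of major depressive disorder (MDD) — offering, say, a
web-based guided self-help programme to adults with subthreshold depressive
symptoms — has to be judged not only on whether it delays depression onset
but on whether it is worth its cost. A trial-based economic evaluation
answers this by combining, over a 12-month horizon and for each participant:

- **costs**, built from resource-use questionnaires (care contacts,
  hospital days, medication, out-of-pocket spending, informal care) priced
  at standardized unit costs, plus productivity losses valued by the human
  capital approach (absenteeism at the gross daily wage; presenteeism as
  affected days weighted by an inefficiency score), under a *health care*
  and a *societal* perspective;
- **effects**: depression-free years (DFY = min(onset, 365.25 d)/365.25 d,
  with onset dated to the midpoint of the reported week or month) and
  quality-adjusted life years (QALY) as the area under the linearly
  interpolated EQ-5D-3L or SF-6D utility curve over the four assessment
  waves (baseline, 6 weeks, 6 months, 12 months).

Missing cost and utility values (monotone dropout, roughly 30% by 12
months) are replaced by conditional-mean regression imputation using
baseline predictors of outcome and of dropout; hospital costs are never
imputed because admissions are too rare to model.

The incremental cost-effectiveness ratio is

```
ICER = (C_INT − C_CTR) / (E_INT − E_CTR) = ΔC / ΔE
```

estimated as the treatment coefficients of a two-equation seemingly
unrelated regression (SUR: cost on arm; effect on arm, fitted by feasible
GLS so the residuals may correlate). Sampling uncertainty is handled by a
nonparametric bootstrap of the patient-level data (2,500 replicates,
stratified within arm): percentile confidence intervals, shares of the
cost-effectiveness plane quadrants, and the cost-effectiveness
acceptability curve

```
CEAC:  p(λ) = P(λ·ΔE − ΔC > 0)
```

giving the probability the intervention is cost-effective at each
willingness-to-pay ceiling λ. When the bootstrap ΔE distribution straddles
zero, no ray through the origin excludes α/2 of the replicates and the ICER
interval is reported as undefined rather than as a misleading pair of
numbers.

## Worked example

```
python examples/run_full_evaluation.py
```

simulates the default trial (202 intervention / 204 control participants),
imputes, and runs the bootstrap CEA. Output (seed 1):

```
      intervention: intervention     299 control      10 incremental    289
 total_health_care: intervention     880 control     893 incremental    -12
    total_societal: intervention    4496 control    4293 incremental    202

main/societal/DFY: dC 202 (-736 to 1087), dE 0.11 (0.04 to 0.17),
    ICER 1863 (-7874 to 12551), NE/NW/SE/SW 67/0/33/0%
main/societal/EQ5D: dC 202 (-749 to 1101), dE 0.00 (-0.02 to 0.02),
    ICER 50103^d, NE/NW/SE/SW 44/24/22/10%
...
At a willingness to pay of €20,000 per depression-free year, the
probability that the intervention is cost-effective (societal perspective)
is 99%.
```

Read: the programme costs €289 more per participant than the control
programme; total costs are slightly higher under the societal perspective
(ΔC = €202) while the intervention gains 0.11 depression-free years, an
ICER of €1,863 per DFY. Two thirds of the bootstrap replicates land in the
north-east quadrant (more health at more cost) and one third in the
south-east (dominance). The EQ-5D QALY gain is indistinguishable from zero,
so its ICER interval carries the undefined-CI footnote (`^d`). Other
examples walk through costing (`costing_walkthrough.py`), the generator
(`simulate_cohort.py`) and the survival analysis (`survival_analysis.py`).

A thin CLI wraps the same pipeline:

```
depcea simulate --out cohort/ --seed 1
depcea analyze --cohort cohort/ --out results/
depcea report --results results/
```

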