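# Methods

This note documents the models implemented in `depcea`, the calibration of
the synthetic-trial generator, and the numerical and design choices made
where the underlying methodology leaves room.

## Study design being emulated

A two-arm pragmatic randomized prevention trial in adults with subthreshold
depression: a web-based guided self-help intervention on top of usual care
(n = 202) versus enhanced usual care (web-based psycho-education, n = 204),
followed for 12 months. Assessments at baseline, 6 weeks, 6 months and 12
months; resource use collected by a TiC-P-style questionnaire with a
3-month recall window at the 6- and 12-month waves; onset of major
depression dated by diagnostic interview with life-chart anchoring. Costs
are expressed in 2013 Euro (consumer-price index factor 1.04 applied where
quantities predate the reference year) and convertible to pound sterling at
£0.85 per €.

## Costing

Each resource-use quantity maps to exactly one cost category. Unit prices
(€, 2013): GP visit 20.92, internist consult 68.06, psychiatrist session
46.55, psychotherapist session 81.44, mental-hospital inpatient day 335.52,
psychosomatic-clinic day 306.41, travel 0.30/km, informal care and domestic
help 18.33/h (shadow price), participant time 23.10/h, programme costs 299
(intervention) and 10 (control) per participant. Two aggregate contact
categories have no single guideline price and use configurable defaults
chosen as realistic German 2013 tariffs: other medical specialist
(physiotherapist/occupational therapist) €25 per contact and psychiatric
day care €100 per day.

Antidepressant costs use a per-day price formed from the three largest
packages of an agent: each package's price per defined daily dose is mixed
as 0.89 × statutory + 0.11 × private (the statutorily insured population
share) and averaged across packages; the default record represents a
generic SSRI at ≈ €0.55/day.

Productivity losses follow the human capital approach: absenteeism = days
absent × gross daily wage; presenteeism = affected days × (1 − rating/10) ×
wage, where rating is self-assessed efficiency on a 0–10 scale. Private
therapist spending, copayments and over-the-counter drugs enter as directly
reported € amounts.

The recall window covers 3 months, so quantities reported at the 6- and
12-month waves are multiplied by an extrapolation factor (default 2) to
cover each 6-month interval; annual cost is the sum of the two costed
waves. The *health care* perspective sums programme, contact, inpatient,
day-care, medication, copayment and OTC categories (this composition
reproduces the published control-arm total of €768 exactly); the *societal*
perspective adds private therapist, informal care, domestic help, travel
and productivity losses. The opportunity cost of participant time is
computed as its own category but excluded from both totals by default
(configurable), since the published cost table carries no such row.
No discounting is applied over the 12-month horizon.

## Effect measures

**Depression-free years.** DFY = min(onset day, 365.25)/365.25; a censored
participant scores exactly 1. Onset reports at week or month granularity
resolve to window start + 3 days and + 15 days respectively. The year is
365.25 days (52.1786 weeks), so 43 depression-free weeks correspond to 0.82
DFY and the restricted-mean-survival and mean-DFY computations agree to
machine precision.

**QALYs.** Trapezoid-rule area under the utilities at wave times 0, 42/365.25,
0.5 and 1.0 years, separately for EQ-5D-3L (range −0.594–1) and SF-6D
(0.30–1). Utilities enter as precomputed index values; no value-set scoring
is performed. No baseline adjustment is made (baseline utilities are
balanced by design).

## Missing data

Dropout is monotone; onset is treated as fully observed for the
intention-to-treat sample (diagnostic interviews cover the full follow-up),
so imputation concerns wave utilities and wave-specific category costs
only. For each target, baseline candidates (arm, age, sex, employment,
baseline severity, baseline utilities) are screened univariably — OLS on
the observed target values for outcome prediction, logistic regression on
the wave's missingness indicator for dropout prediction — retaining
candidates at p < 0.05; the union of the two sets enters a joint OLS fit
whose predictions replace the missing values (conditional mean, no residual
noise — single deterministic imputation, not multiple imputation). Observed
values are never altered, so the pass is idempotent. Hospital categories
(inpatient, day care) are never imputed: missing hospital costs contribute
zero, and their influence is probed by the sensitivity analysis that
removes them entirely. Every selection decision and coefficient is written
to an audit CSV. Whether the original procedure screened univariably or
multivariably, and at which α, is not specified anywhere; the univariable
p < 0.05 screen is this package's documented choice and both the threshold
and candidate set are arguments.

## Incremental analysis

ΔC and ΔE are the treatment coefficients of the two-equation SUR system
(cost ~ arm; effect ~ arm) estimated by feasible GLS with the residual
covariance taken from the per-equation OLS residuals. With identical
regressors in both equations the SUR coefficients equal the per-equation
difference in means exactly — this algebraic identity is used as a test
oracle — but joint estimation reports the cross-equation residual
correlation and keeps cost and effect resampled jointly. If the estimated
residual covariance is singular (degenerate inputs) the estimator falls
back to OLS, which is exact in that case.

The bootstrap resamples participants with replacement, stratified within
arm so every replicate preserves the 202/204 arm sizes and remains
estimable (an unstratified mode is available). Defaults: B = 2,500,
deterministic given an integer seed. From the replicate cloud the package
derives equal-tail percentile CIs for ΔC and ΔE, quadrant shares (ΔE = 0 is
assigned east — a measure-zero event for continuous data, fixed for
reproducibility; ΔC = 0 counts as "not more costly"), and the CEAC
p(λ) = B⁻¹·Σ 1[λ·ΔE_b − ΔC_b > 0] over a default λ grid of €0–50,000 in
steps of €50.

The ICER interval uses the percentile-of-angle method: replicates are
ordered counterclockwise by atan2(ΔC, ΔE) starting from due south, and the
interval spans the central 1 − α of that ordering. When the α/2 and 1 − α/2
percentiles of ΔE bracket zero, no ray through the origin leaves α/2 of the
mass on each side and the interval is reported as undefined (rendered with
a footnote marker rather than numbers).

## Survival analysis

Cox proportional hazards of time to onset (weeks) on treatment, Breslow tie
handling (week-resolution dating produces ties). Concurrent antidepressant
use at baseline enters post hoc and is pruned (model refit treatment-only)
when non-significant at p ≥ 0.05. Restricted mean depression-free survival
is the area under the Kaplan-Meier curve up to 52.1786 weeks with a
Greenwood-type variance: Var = Σ_events A(t_i)² d_i /(n_i(n_i − d_i)),
where A(t) is the remaining area from t to the horizon. With censoring only
at the horizon this reduces exactly to the sampling variance of the mean of
min(T, horizon), which is verified in a test.

## Synthetic-trial generator

The generator is first-class, tested code; its defaults *are* the emulated
study conditions, fixed once:

- **Arms**: 202/204. **Onset**: exponential per arm, censored at 365.25
  days, hazards solved so the restricted mean depression-free survival is
  43 (intervention) and 37 (control) weeks — an incremental 0.115 DFY. A
  one-parameter stand-in per arm suffices because only the restricted means
  are calibration targets.
- **Utilities**: Gaussian-copula AR(1) across waves (ρ = 0.7) with
  truncated-normal margins on the instrument range; the location of each
  wave's margin is solved numerically so the *truncated* mean equals the
  configured wave mean. Defaults: baseline EQ-5D 0.74 (SD 0.15) in both
  arms; follow-up wave means chosen so the AUC means reproduce QALY levels
  of ≈0.78/0.77 (EQ-5D) and ≈0.71/0.67 (SF-6D). Truncation at 1 makes the
  realized baseline mean ≈0.737 and SD ≈0.14; the package treats the
  configured values as targets for the truncated distribution's location.
- **Costs**: two-part draws per category and recall window — Bernoulli
  any-use × gamma positive part (shape ≤ 1 for the heavily skewed
  categories), giving exact zeros and SDs exceeding means as in real
  resource-use data. The per-window positive-part mean is back-solved from
  the configured *annual* mean cost, the zero probability, the number of
  costed waves, the extrapolation factor and the unit value, so configured
  annual category means are exact population expectations. Default annual
  means per arm equal the published per-category means (splits of
  aggregated rows, e.g. GP vs internist, are the package's choice).
  Quantities are continuous rather than integer counts; only their costed
  values matter downstream.
- **Severity coupling**: a standard-normal baseline-severity score z shifts
  utilities by −0.04·z per wave, scales positive cost draws by
  exp(0.3·z − 0.045) (mean-one, so calibration is preserved) and shifts the
  dropout log-odds by +0.4·z. This makes dropout missing-at-random given
  arm and severity, with complete-case analysis genuinely biased — which is
  what lets the tests demonstrate that the imputation reduces bias.
- **Dropout**: monotone, conditional per-wave probabilities calibrated by
  Gauss–Hermite quadrature so marginal retention is ≈90.1%, 80.1% and 70.4%
  with 12-month retention 66% vs 75% by arm (higher dropout under
  intervention).
- **Wages/employment**: 75% employed; log-normal gross daily wage, mean
  €120, log-SD 0.4; efficiency on presenteeism days uniform on 3–8.
- A single master seed spawns independent named streams (demographics,
  onset, utilities, costs, missingness) so stages are individually
  reproducible; the cohort is a pure function of (config, seed).

What the generator does *not* emulate: item-level questionnaire responses,
onset-dependent utility or cost trajectories (costs, utilities and onset
are conditionally independent given arm and severity), seasonal or
calendar-time effects, and non-monotone intermittent missingness. Passing
tests therefore demonstrate correctness of the estimators under a
plausible, calibrated data-generating process — not trial realism beyond
the calibrated margins.

## Problem sizes and tolerances

Calibration and oracle tests run at n = 10,000–50,000 per arm where
closed-form comparisons need small Monte-Carlo error (1% tolerances on
restricted means; 10% on skewed cost-category means); the end-to-end
parameter-recovery check runs the full pipeline at n = 5,000/arm with
B = 1,000 and requires the recovered ΔDFY and societal ΔC to lie within two
bootstrap standard errors of the configured values. Exact identities (SUR
vs difference-in-means, AUC vs fine-grid integration, RMST/DFY consistency)
are asserted at 1e-8–1e-10. Published-arithmetic checks (ICERs from printed
incrementals, €768 perspective composition, retention percentages) are
exact after the stated display rounding: whole € for costs and ICERs
(half away from zero), two decimals for effects, whole percent for quadrant
shares using largest-remainder rounding so each row totals 100%.

## Known limitations

- Single deterministic regression imputation understates between-imputation
  uncertainty relative to multiple imputation; the bootstrap captures only
  sampling variability of the completed data.
- The published societal category means sum to slightly more than the
  published societal totals (the unrounded source data are unavailable);
  the generator calibrates to the per-category means, so its configured
  incremental total cost (€137 health care, €98 societal) differs from the
  printed €136/€143 by rounding accumulation.
- Fieller and bias-corrected/accelerated intervals, net-benefit regression
  with covariates, friction-cost productivity valuation and modelling
  beyond the trial horizon are out of scope.
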