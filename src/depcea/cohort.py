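"""Synthetic two-arm prevention-trial generator.

Produces patient-level data with the structure the economic evaluation
assumes: arm assignment, baseline covariates, an exponential time to onset of
major depression censored at 12 months, truncated-normal utility trajectories
correlated across waves, zero-inflated gamma resource-use quantities whose
population category means equal the configured annual cost targets, and
monotone missing-at-random dropout driven by arm and baseline symptom
severity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr
from scipy.stats import truncnorm

from .config import (
    ARMS,
    COST_WAVES,
    ConfigError,
    N_WAVES,
    SyntheticTrialConfig,
    UTILITY_FLOORS,
    UnitPriceTable,
    WAVE_TIMES,
    YEAR_DAYS,
    WEEKS_PER_YEAR,
)
from .costing import (
    DEFAULT_MEDICATION_PACKAGES,
    FIELD_VALUATION,
    HEALTH_CARE_CATEGORIES,
    HOSPITAL_CATEGORIES,
    RESOURCE_FIELDS,
    SOCIETAL_ONLY_CATEGORIES,
    medication_per_day_price,
)

#: self-rated efficiency on presenteeism days, uniform on this range
EFFICIENCY_RANGE = (3.0, 8.0)
_EFFICIENCY_FACTOR = 1.0 - (sum(EFFICIENCY_RANGE) / 2.0) / 10.0  # E[1 - r/10]

PARTICIPANT_COLUMNS = [
    "pid", "arm", "age", "sex", "employed", "gross_daily_wage",
    "baseline_symptoms", "symptom_z", "antidepressant_use", "onset_day",
    "event", "intervention_hours",
]

#: share on a stable antidepressant dose at entry (allowed by the pragmatic
#: design); independent of onset, so covariate pruning removes it
BASELINE_ANTIDEPRESSANT_RATE = 0.12


@dataclass
class Cohort:
    """Patient-level trial data: one participant table, one wave-long table."""

    participants: pd.DataFrame
    waves: pd.DataFrame

    def copy(self) -> "Cohort":
        return Cohort(self.participants.copy(), self.waves.copy())

    def write_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(directory / "participants.csv", index=False)
        self.waves.to_csv(directory / "waves.csv", index=False)

    @classmethod
    def read_csv(cls, directory) -> "Cohort":
        directory = Path(directory)
        try:
            participants = pd.read_csv(directory / "participants.csv")
            waves = pd.read_csv(directory / "waves.csv")
        except FileNotFoundError as err:
            raise FileNotFoundError(
                f"cohort directory {directory} must contain participants.csv "
                f"and waves.csv: {err}") from err
        missing = set(PARTICIPANT_COLUMNS) - set(participants.columns)
        if missing:
            raise ValueError(f"participants.csv missing columns: {sorted(missing)}")
        waves["observed"] = waves["observed"].astype(bool)
        participants["event"] = participants["event"].astype(bool)
        participants["employed"] = participants["employed"].astype(bool)
        participants["antidepressant_use"] = (
            participants["antidepressant_use"].astype(bool))
        return cls(participants, waves)


# -- onset ---------------------------------------------------------------------

def sample_onset_days(hazard_per_week: float, horizon_days: float,
                      rng: np.random.Generator, size: int) -> np.ndarray:
    """Exponential onset times in days, NaN where censored at the horizon."""
    if hazard_per_week < 0:
        raise ConfigError("onset hazard must be >= 0")
    if hazard_per_week == 0:
        return np.full(size, np.nan)
    weeks = rng.exponential(1.0 / hazard_per_week, size)
    days = weeks * 7.0
    return np.where(days <= horizon_days, days, np.nan)


# -- utilities -----------------------------------------------------------------

def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal on [lo, hi] whose mean is target_mean."""
    def mean_at(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd)
    return brentq(lambda loc: mean_at(loc) - target_mean,
                  lo - 10 * sd, hi + 10 * sd)


def _sample_utilities(config: SyntheticTrialConfig, instrument: str,
                      arm_idx: np.ndarray, symptom_z: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """(n, 4) utility matrix: AR(1) Gaussian copula, truncated-normal margins."""
    n = arm_idx.size
    sd = config.utility_sd[instrument]
    lo, hi = UTILITY_FLOORS[instrument], 1.0
    rho = config.utility_rho
    # latent standard-normal AR(1) across waves
    z = np.empty((n, N_WAVES))
    z[:, 0] = rng.standard_normal(n)
    for w in range(1, N_WAVES):
        z[:, w] = rho * z[:, w - 1] + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    u = np.empty((n, N_WAVES))
    for ai, arm in enumerate(ARMS):
        mask = arm_idx == ai
        if not mask.any():
            continue
        for w in range(N_WAVES):
            base = _truncnorm_loc(
                config.utility_mean_by_wave_and_arm[instrument][arm][w], sd, lo, hi)
            loc = base - config.utility_symptom_coef * symptom_z[mask]
            a, b = (lo - loc) / sd, (hi - loc) / sd
            u[mask, w] = truncnorm.ppf(ndtr(z[mask, w]), a, b, loc=loc, scale=sd)
    return u


# -- resource use ---------------------------------------------------------------

def _unit_value(field: str, prices: UnitPriceTable, med_per_day: float,
                config: SyntheticTrialConfig) -> float:
    """Expected € per unit of quantity, used to back out quantity means."""
    _, rule = FIELD_VALUATION[field]
    if rule.startswith("price:"):
        return getattr(prices, rule.split(":", 1)[1])
    if rule == "euro":
        return 1.0
    if rule == "medication":
        return med_per_day
    if rule == "wage_absent":
        return config.wage.employment_rate * config.wage.mean
    if rule == "wage_presenteeism":
        return (config.wage.employment_rate * config.wage.mean
                * _EFFICIENCY_FACTOR)
    raise KeyError(rule)  # pragma: no cover


def _sample_quantities(config: SyntheticTrialConfig, field: str,
                       arm_idx: np.ndarray, employed: np.ndarray,
                       symptom_z: np.ndarray, unit_value: float,
                       rng: np.random.Generator) -> np.ndarray:
    """(n, n_cost_waves) two-part quantity draws for one panel field."""
    params = config.cost_category_params[field]
    n = arm_idx.size
    n_w = len(COST_WAVES)
    q = np.zeros((n, n_w))
    c = config.cost_symptom_coef
    # mean-one multiplier coupling costs to baseline severity
    mult = np.exp(c * symptom_z - 0.5 * c ** 2)
    wage_valued = FIELD_VALUATION[field][1].startswith("wage")
    for ai, arm in enumerate(ARMS):
        mask = arm_idx == ai
        if wage_valued:
            mask = mask & employed
        m = mask.sum()
        target = params.annual_mean[arm]
        if m == 0 or target == 0 or params.zero_prob >= 1.0:
            continue
        pos_mean = target / (
            n_w * config.extrapolation_factor
            * (1.0 - params.zero_prob) * unit_value)
        any_use = rng.random((m, n_w)) >= params.zero_prob
        draws = rng.gamma(params.shape, pos_mean / params.shape, (m, n_w))
        q[mask] = any_use * draws * mult[mask, None]
    return q


# -- missingness -----------------------------------------------------------------

def _logit_offset(p: float, gamma: float) -> float:
    """Intercept a with E_Z[expit(a + gamma Z)] = p for Z ~ N(0,1)."""
    if p <= 0:
        return -np.inf
    if p >= 1:
        return np.inf
    if gamma == 0:
        return float(np.log(p / (1 - p)))
    nodes, weights = np.polynomial.hermite_e.hermegauss(60)
    total = weights.sum()

    def marginal(a):
        return float(np.sum(weights * expit(a + gamma * nodes)) / total) - p

    return brentq(marginal, -30, 30)


def apply_missingness(cohort: Cohort,
                      dropout_prob_by_wave_and_arm: dict,
                      symptom_coef: float = 0.0,
                      seed: int | np.random.Generator = 0) -> Cohort:
    """Impose monotone wave dropout; returns a new cohort with observed flags.

    Per arm and wave, the conditional dropout probability among participants
    still observed is the configured value in expectation; on the logit scale
    it shifts by ``symptom_coef`` per SD of baseline symptoms (MAR given arm
    and severity). Once dropped, all later waves are unobserved, and their
    utilities and resource-use quantities are set to missing.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    parts = cohort.participants
    n = len(parts)
    z = parts["symptom_z"].to_numpy(float)
    arm = parts["arm"].to_numpy()
    observed = np.ones((n, N_WAVES), bool)
    for a in ARMS:
        probs = dropout_prob_by_wave_and_arm[a]
        if len(probs) != N_WAVES - 1:
            raise ConfigError("need one dropout probability per follow-up wave")
        amask = arm == a
        alive = amask.copy()
        for w, p in enumerate(probs, start=1):
            if not 0 <= p <= 1:
                raise ConfigError("dropout probabilities must be in [0,1]")
            offset = _logit_offset(p, symptom_coef)
            pr = expit(offset + symptom_coef * z)
            drop = alive & (rng.random(n) < pr)
            alive = alive & ~drop
            observed[amask, w:] &= alive[amask, None]
    waves = cohort.waves.copy()
    pid_index = {pid: i for i, pid in enumerate(parts["pid"])}
    rows_p = waves["pid"].map(pid_index).to_numpy()
    waves["observed"] = observed[rows_p, waves["wave"].to_numpy()]
    hidden = ~waves["observed"].to_numpy()
    for col in ("eq5d", "sf6d", "efficiency_rating", *RESOURCE_FIELDS):
        if col in waves:
            waves.loc[hidden, col] = np.nan
    return Cohort(parts.copy(), waves)


# -- cohort generation ------------------------------------------------------------

def generate_cohort(config: SyntheticTrialConfig,
                    seed: int | None = None,
                    prices: UnitPriceTable | None = None) -> Cohort:
    """Generate a complete synthetic trial cohort (pure function of config+seed).

    Missingness is applied according to the configured dropout schedule; the
    fully observed values can be regenerated by setting all dropout
    probabilities to zero. Onset of depression is always observed
    (diagnostic interviews cover the full follow-up for the ITT sample).
    """
    config.validate()
    prices = prices or UnitPriceTable()
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("demo", "onset", "EQ5D", "SF6D", "costs", "missing"), ss.spawn(6))}

    n = config.n_intervention + config.n_control
    arm_idx = np.concatenate([
        np.zeros(config.n_intervention, int), np.ones(config.n_control, int)])
    arm = np.array(ARMS)[arm_idx]
    rng = streams["demo"]
    age = np.clip(rng.normal(45, 12, n), 18, 80).round(0)
    sex = np.where(rng.random(n) < 0.7, "female", "male")
    employed = rng.random(n) < config.wage.employment_rate
    mu = np.log(config.wage.mean) - 0.5 * config.wage.sigma ** 2
    wage = np.where(employed, rng.lognormal(mu, config.wage.sigma, n), 0.0)
    symptom_z = rng.standard_normal(n)
    symptoms = config.symptom_mean + config.symptom_sd * symptom_z
    antidep = rng.random(n) < BASELINE_ANTIDEPRESSANT_RATE

    onset = np.empty(n)
    for ai, a in enumerate(ARMS):
        mask = arm_idx == ai
        onset[mask] = sample_onset_days(
            config.onset_hazard_per_week[a], YEAR_DAYS,
            streams["onset"], int(mask.sum()))
    event = ~np.isnan(onset)

    participants = pd.DataFrame({
        "pid": np.arange(n),
        "arm": arm,
        "age": age,
        "sex": sex,
        "employed": employed,
        "gross_daily_wage": wage,
        "baseline_symptoms": symptoms,
        "symptom_z": symptom_z,
        "antidepressant_use": antidep,
        "onset_day": onset,
        "event": event,
        "intervention_hours": [config.intervention_hours[a] for a in arm],
    })

    util = {inst: _sample_utilities(config, inst, arm_idx, symptom_z,
                                    streams[inst])
            for inst in ("EQ5D", "SF6D")}

    med_pd = medication_per_day_price(
        DEFAULT_MEDICATION_PACKAGES, prices.statutory_share)
    qty = {fld: _sample_quantities(
        config, fld, arm_idx, employed, symptom_z,
        _unit_value(fld, prices, med_pd, config), streams["costs"])
        for fld in RESOURCE_FIELDS}
    eff_lo, eff_hi = EFFICIENCY_RANGE
    efficiency = streams["costs"].uniform(eff_lo, eff_hi, (n, len(COST_WAVES)))

    rows = []
    for w in range(N_WAVES):
        df = pd.DataFrame({
            "pid": participants["pid"],
            "arm": arm,
            "wave": w,
            "time_years": WAVE_TIMES[w],
            "observed": True,
            "eq5d": util["EQ5D"][:, w],
            "sf6d": util["SF6D"][:, w],
            "gross_daily_wage": wage,
        })
        if w in COST_WAVES:
            ci = COST_WAVES.index(w)
            df["efficiency_rating"] = efficiency[:, ci]
            for fld in RESOURCE_FIELDS:
                df[fld] = qty[fld][:, ci]
        else:
            df["efficiency_rating"] = np.nan
            for fld in RESOURCE_FIELDS:
                df[fld] = np.nan
        rows.append(df)
    waves = pd.concat(rows, ignore_index=True).sort_values(
        ["pid", "wave"], ignore_index=True)

    cohort = Cohort(participants, waves)
    return apply_missingness(
        cohort, config.dropout_prob_by_wave_and_arm,
        config.dropout_symptom_coef, streams["missing"])


# -- analytic expectations (used for calibration checks) ---------------------------

def expected_arm_costs(config: SyntheticTrialConfig,
                       prices: UnitPriceTable | None = None,
                       perspective: str = "societal",
                       include_opportunity_cost: bool = False,
                       drop_hospitalization: bool = False) -> dict:
    """Population mean annual cost per arm implied by the generator config."""
    prices = prices or UnitPriceTable()
    if perspective == "health_care":
        cats = set(HEALTH_CARE_CATEGORIES)
    elif perspective == "societal":
        cats = set(HEALTH_CARE_CATEGORIES) | set(SOCIETAL_ONLY_CATEGORIES)
    else:
        raise KeyError(perspective)
    if drop_hospitalization:
        cats -= set(HOSPITAL_CATEGORIES)
    out = {}
    for a in ARMS:
        total = 0.0
        if "intervention" in cats:
            total += (prices.intervention_cost if a == "intervention"
                      else prices.control_program_cost)
        for fld, params in config.cost_category_params.items():
            if FIELD_VALUATION[fld][0] in cats:
                total += params.annual_mean[a]
        if include_opportunity_cost:
            total += config.intervention_hours[a] * prices.opportunity_cost
        out[a] = total
    return out


def expected_mean_dfw(config: SyntheticTrialConfig) -> dict:
    """Population mean depression-free weeks per arm (restricted to 1 year)."""
    out = {}
    for a in ARMS:
        lam = config.onset_hazard_per_week[a]
        out[a] = (WEEKS_PER_YEAR if lam == 0
                  else (1.0 - np.exp(-lam * WEEKS_PER_YEAR)) / lam)
    return out


def expected_delta_dfy(config: SyntheticTrialConfig) -> float:
    """Configured incremental depression-free years (intervention - control)."""
    dfw = expected_mean_dfw(config)
    return (dfw["intervention"] - dfw["control"]) / WEEKS_PER_YEAR
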