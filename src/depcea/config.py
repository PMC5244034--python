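"""Configuration objects for the trial emulation and the economic analysis.

Monetary values are Euro (2013 price level unless stated otherwise); time is
measured in years since randomization with a 12-month horizon of 365.25 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

YEAR_DAYS = 365.25
WEEKS_PER_YEAR = YEAR_DAYS / 7.0  # 52.1786, displayed as 52.18

ARMS = ("intervention", "control")
#: assessment schedule: baseline, post-treatment (6 weeks), 6 and 12 months
WAVE_TIMES = (0.0, 42.0 / YEAR_DAYS, 0.5, 1.0)
N_WAVES = 4
#: waves at which the resource-use questionnaire covers the follow-up period
COST_WAVES = (2, 3)

UTILITY_FLOORS = {"EQ5D": -0.594, "SF6D": 0.30}


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class UnitPriceTable:
    """Unit cost prices (€, 2013) applied to resource-use quantities.

    Contact and inpatient prices follow standardized German costing
    guidelines; ``other_specialist`` and ``daycare`` are configurable
    tariffs (no single guideline price exists for those aggregates).
    """

    gp: float = 20.92                       # €/visit
    internist: float = 68.06                # €/consult
    psychiatrist: float = 46.55             # €/session
    psychotherapist: float = 81.44          # €/session
    other_specialist: float = 25.00         # €/contact
    inpatient_mental: float = 335.52        # €/day
    inpatient_psychosomatic: float = 306.41  # €/day
    daycare: float = 100.00                 # €/day
    travel: float = 0.30                    # €/km
    informal_care: float = 18.33            # €/h shadow price
    domestic_help: float = 18.33            # €/h shadow price
    opportunity_cost: float = 23.10         # €/h of participant time
    intervention_cost: float = 299.0        # € per intervention participant
    control_program_cost: float = 10.0      # € per control participant
    statutory_share: float = 0.89           # statutorily insured share
    cpi_index_factor: float = 1.04          # indexing to the 2013 price level
    euro_to_gbp: float = 0.85               # £ per €

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ConfigError(f"unit price {name!r} must be >= 0, got {value}")
        for name in ("statutory_share", "cpi_index_factor", "euro_to_gbp"):
            if not 0 < getattr(self, name):
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.statutory_share <= 1:
            raise ConfigError("statutory_share must be in (0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "UnitPriceTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        table = cls(**data)
        table.validate()
        return table


@dataclass
class MedicationPackage:
    """One package size of an antidepressant agent."""

    statutory_price: float  # € pharmacy retail price, statutory discount
    private_price: float    # € pharmacy retail price, private insurance
    ddd_count: float        # defined daily doses covered by the package


#: three largest packages of a representative generic SSRI; per-day price
#: works out to ≈ €0.55 after statutory weighting
DEFAULT_MEDICATION_PACKAGES = (
    MedicationPackage(19.50, 22.10, 30),
    MedicationPackage(28.40, 32.90, 50),
    MedicationPackage(52.80, 60.40, 100),
)


@dataclass
class CostCategoryParams:
    """Two-part (zero-inflated gamma) generator settings for one resource item.

    ``annual_mean`` is the target mean annual cost (€) per arm; the generator
    back-solves the per-wave positive-part quantity mean from it, so the
    configured value is the exact population expectation of the costed
    category.
    """

    annual_mean: dict[str, float]  # arm -> € per participant-year
    zero_prob: float               # P(no use in a recall window)
    shape: float = 1.0             # gamma shape of the positive part

    def validate(self, name: str) -> None:
        if not 0 <= self.zero_prob <= 1:
            raise ConfigError(f"{name}: zero_prob must be in [0,1]")
        if self.shape <= 0:
            raise ConfigError(f"{name}: gamma shape must be > 0")
        for arm, m in self.annual_mean.items():
            if arm not in ARMS:
                raise ConfigError(f"{name}: unknown arm {arm!r}")
            if m < 0:
                raise ConfigError(f"{name}: annual mean must be >= 0")
        if self.zero_prob == 1.0 and any(v > 0 for v in self.annual_mean.values()):
            raise ConfigError(f"{name}: zero_prob 1 with a positive mean target")


def _default_cost_params() -> dict[str, CostCategoryParams]:
    # annual mean € (intervention, control), per-window zero probability, shape
    spec = {
        "gp_visits": (85, 70, 0.45, 1.0),
        "internist_visits": (57, 47, 0.70, 1.0),
        "psychiatrist_sessions": (47, 70, 0.85, 1.0),
        "psychotherapist_sessions": (70, 105, 0.85, 1.0),
        "other_specialist_contacts": (243, 236, 0.50, 1.0),
        "inpatient_mental_days": (30, 80, 0.997, 1.0),
        "inpatient_psychosomatic_days": (18, 43, 0.997, 1.0),
        "daycare_days": (0, 35, 0.998, 1.0),
        "antidepressant_days": (12, 20, 0.90, 1.0),
        "private_therapist_spend": (137, 117, 0.75, 1.0),
        "copayments": (27, 30, 0.60, 1.0),
        "otc_spend": (17, 22, 0.55, 1.0),
        "informal_care_hours": (323, 384, 0.80, 0.8),
        "domestic_help_hours": (143, 120, 0.85, 0.8),
        "travel_km": (29, 28, 0.40, 1.0),
        "absent_days": (1475, 1172, 0.60, 0.8),
        "presenteeism_days": (1696, 2021, 0.45, 0.8),
    }
    out = {}
    for name, (mi, mc, p0, k) in spec.items():
        zp = p0 if not (mi == 0 and mc == 0) else 1.0
        out[name] = CostCategoryParams(
            annual_mean={"intervention": float(mi), "control": float(mc)},
            zero_prob=zp,
            shape=k,
        )
    # intervention arm never uses day care in the emulated trial
    return out


@dataclass
class WageParams:
    """Gross daily wage distribution (log-normal) and employment rate."""

    mean: float = 120.0        # €/day gross
    sigma: float = 0.4         # log-scale SD
    employment_rate: float = 0.75

    def validate(self) -> None:
        if self.mean < 0 or self.sigma < 0:
            raise ConfigError("wage mean and sigma must be >= 0")
        if not 0 <= self.employment_rate <= 1:
            raise ConfigError("employment_rate must be in [0,1]")


def onset_hazard_from_mean_weeks(mean_weeks: float,
                                 horizon_weeks: float = WEEKS_PER_YEAR) -> float:
    """Exponential hazard/week whose restricted mean equals ``mean_weeks``.

    Solves (1 - exp(-λT)) / λ = m for λ; m = T means no events (hazard 0).
    """
    if not 0 < mean_weeks <= horizon_weeks:
        raise ConfigError("mean depression-free weeks must be in (0, horizon]")
    if mean_weeks == horizon_weeks:
        return 0.0
    return brentq(
        lambda lam: (1.0 - np.exp(-lam * horizon_weeks)) / lam - mean_weeks,
        1e-12, 10.0,
    )


@dataclass
class SyntheticTrialConfig:
    """Parameters of the synthetic two-arm prevention trial.

    Defaults emulate the published study conditions: 202/204 participants,
    mean depression-free survival of 43 vs 37 weeks over 12 months, baseline
    EQ-5D utility 0.74 (SD 0.15) in both arms, ~70% retention at 12 months
    with higher 12-month dropout in the intervention arm, and zero-inflated
    right-skewed cost categories whose annual means match the published
    per-category arm means.
    """

    n_intervention: int = 202
    n_control: int = 204
    onset_hazard_per_week: dict[str, float] = field(default_factory=lambda: {
        "intervention": onset_hazard_from_mean_weeks(43.0),
        "control": onset_hazard_from_mean_weeks(37.0),
    })
    utility_mean_by_wave_and_arm: dict[str, dict[str, tuple]] = field(
        default_factory=lambda: {
            "EQ5D": {
                "intervention": (0.74, 0.78, 0.78, 0.79),
                "control": (0.74, 0.77, 0.77, 0.78),
            },
            "SF6D": {
                "intervention": (0.68, 0.71, 0.71, 0.72),
                "control": (0.66, 0.67, 0.67, 0.675),
            },
        })
    utility_sd: dict[str, float] = field(
        default_factory=lambda: {"EQ5D": 0.15, "SF6D": 0.08})
    utility_rho: float = 0.7       # AR(1) correlation across waves
    cost_category_params: dict[str, CostCategoryParams] = field(
        default_factory=_default_cost_params)
    wage: WageParams = field(default_factory=WageParams)
    #: conditional per-wave dropout probability among those still observed,
    #: waves 1..3; 12-month dropout is higher under intervention
    dropout_prob_by_wave_and_arm: dict[str, tuple] = field(
        default_factory=lambda: {
            "intervention": (0.099, 0.111, 0.176),
            "control": (0.099, 0.111, 0.066),
        })
    #: log-odds shift of dropout per SD of baseline symptom severity (MAR)
    dropout_symptom_coef: float = 0.4
    #: multiplicative cost shift per SD of baseline symptoms (mean-preserving)
    cost_symptom_coef: float = 0.3
    #: utility decrement per SD of baseline symptoms
    utility_symptom_coef: float = 0.04
    symptom_mean: float = 25.0     # CES-D style score, screened population
    symptom_sd: float = 6.0
    extrapolation_factor: float = 2.0  # 3-month recall -> 6-month interval
    intervention_hours: dict[str, float] = field(
        default_factory=lambda: {"intervention": 3.0, "control": 0.5})
    seed: int = 0

    def validate(self) -> None:
        if self.n_intervention < 0 or self.n_control < 0:
            raise ConfigError("arm sizes must be >= 0")
        for arm in ARMS:
            if self.onset_hazard_per_week.get(arm, 0.0) < 0:
                raise ConfigError("onset hazards must be >= 0")
            for p in self.dropout_prob_by_wave_and_arm.get(arm, ()):
                if not 0 <= p <= 1:
                    raise ConfigError("dropout probabilities must be in [0,1]")
        for inst, by_arm in self.utility_mean_by_wave_and_arm.items():
            if inst not in UTILITY_FLOORS:
                raise ConfigError(f"unknown utility instrument {inst!r}")
            for arm, means in by_arm.items():
                if len(means) != N_WAVES:
                    raise ConfigError(f"{inst}/{arm}: need {N_WAVES} wave means")
                if any(m > 1 for m in means):
                    raise ConfigError(f"{inst}/{arm}: utility means must be <= 1")
        for name, params in self.cost_category_params.items():
            params.validate(name)
        self.wage.validate()
        if self.extrapolation_factor <= 0:
            raise ConfigError("extrapolation_factor must be > 0")

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for inst in d["utility_mean_by_wave_and_arm"]:
            for arm in d["utility_mean_by_wave_and_arm"][inst]:
                d["utility_mean_by_wave_and_arm"][inst][arm] = list(
                    d["utility_mean_by_wave_and_arm"][inst][arm])
        for arm in d["dropout_prob_by_wave_and_arm"]:
            d["dropout_prob_by_wave_and_arm"][arm] = list(
                d["dropout_prob_by_wave_and_arm"][arm])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticTrialConfig":
        data = dict(data)
        if "cost_category_params" in data:
            data["cost_category_params"] = {
                k: (v if isinstance(v, CostCategoryParams)
                    else CostCategoryParams(**v))
                for k, v in data["cost_category_params"].items()
            }
        if "wage" in data and not isinstance(data["wage"], WageParams):
            data["wage"] = WageParams(**data["wage"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTrialConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


EFFECTS = ("DFY", "EQ5D", "SF6D")
PERSPECTIVES = ("societal", "health_care")


@dataclass
class AnalysisConfig:
    """Settings of the cost-effectiveness / cost-utility analysis run."""

    perspectives: Sequence[str] = PERSPECTIVES
    effects: Sequence[str] = ("DFY", "EQ5D")
    sf6d_sensitivity: bool = True          # add SF-6D QALY variant
    drop_hospitalization: bool = True      # add no-hospital-costs variant
    n_bootstrap: int = 2500
    seed: int = 1
    lambda_grid: Sequence[float] = field(
        default_factory=lambda: tuple(np.arange(0, 50001, 50, dtype=float)))
    include_opportunity_cost: bool = False
    extrapolation_factor: float = 2.0
    currency: str = "EUR"

    def validate(self) -> None:
        for p in self.perspectives:
            if p not in PERSPECTIVES:
                raise ConfigError(f"unknown perspective {p!r}")
        for e in self.effects:
            if e not in EFFECTS:
                raise ConfigError(f"unknown effect {e!r}")
        if self.n_bootstrap <= 0:
            raise ConfigError("n_bootstrap must be > 0")
        if any(l < 0 for l in self.lambda_grid):
            raise ConfigError("willingness-to-pay values must be >= 0")

    def variant_effects(self) -> tuple:
        eff = list(self.effects)
        if self.sf6d_sensitivity and "SF6D" not in eff:
            eff.append("SF6D")
        return tuple(eff)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg
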