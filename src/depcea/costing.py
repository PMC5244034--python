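"""Valuation of resource use: unit-price costing, medication weighting,
human-capital productivity losses, perspective totals, indexing/conversion.

Quantities come from a 3-month recall questionnaire administered at the 6- and
12-month waves; each window is extrapolated (default x2) to cover its 6-month
interval, so summing the two costed waves yields annual per-participant costs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    COST_WAVES,
    DEFAULT_MEDICATION_PACKAGES,
    MedicationPackage,
    UnitPriceTable,
)


class SchemaError(KeyError):
    """Unknown resource-use field, category or perspective."""


#: cost-breakdown categories, in report order
CATEGORIES = (
    "intervention", "gp_internist", "mental_health", "other_specialist",
    "inpatient", "daycare", "antidepressants", "private_therapist",
    "copayments", "otc", "informal_care", "domestic_help", "travel",
    "absenteeism", "presenteeism", "opportunity_time",
)

#: direct-medical categories; patient/family and productivity costs are
#: added on top of these under the societal perspective
HEALTH_CARE_CATEGORIES = (
    "intervention", "gp_internist", "mental_health", "other_specialist",
    "inpatient", "daycare", "antidepressants", "copayments", "otc",
)
SOCIETAL_ONLY_CATEGORIES = (
    "private_therapist", "informal_care", "domestic_help", "travel",
    "absenteeism", "presenteeism",
)
#: removed in the no-hospitalization sensitivity analysis
HOSPITAL_CATEGORIES = ("inpatient", "daycare")

#: resource-use panel field -> (breakdown category, valuation rule).
#: rules: price:<key> unit price; euro: reported € amount; medication:
#: weighted per-day price; wage_absent / wage_presenteeism: human capital.
FIELD_VALUATION = {
    "gp_visits": ("gp_internist", "price:gp"),
    "internist_visits": ("gp_internist", "price:internist"),
    "psychiatrist_sessions": ("mental_health", "price:psychiatrist"),
    "psychotherapist_sessions": ("mental_health", "price:psychotherapist"),
    "other_specialist_contacts": ("other_specialist", "price:other_specialist"),
    "inpatient_mental_days": ("inpatient", "price:inpatient_mental"),
    "inpatient_psychosomatic_days": ("inpatient", "price:inpatient_psychosomatic"),
    "daycare_days": ("daycare", "price:daycare"),
    "antidepressant_days": ("antidepressants", "medication"),
    "private_therapist_spend": ("private_therapist", "euro"),
    "copayments": ("copayments", "euro"),
    "otc_spend": ("otc", "euro"),
    "informal_care_hours": ("informal_care", "price:informal_care"),
    "domestic_help_hours": ("domestic_help", "price:domestic_help"),
    "travel_km": ("travel", "price:travel"),
    "absent_days": ("absenteeism", "wage_absent"),
    "presenteeism_days": ("presenteeism", "wage_presenteeism"),
}
RESOURCE_FIELDS = tuple(FIELD_VALUATION)
#: never imputed; missing values contribute 0 (too few admissions to model)
HOSPITAL_FIELDS = tuple(
    f for f, (cat, _) in FIELD_VALUATION.items() if cat in HOSPITAL_CATEGORIES)


# -- medication ---------------------------------------------------------------

def medication_per_day_price(
    packages: Sequence[MedicationPackage] = DEFAULT_MEDICATION_PACKAGES,
    statutory_share: float = 0.89,
) -> float:
    """Per-day antidepressant price: mean over the 3 largest packages of the
    statutory/private mix of the per-defined-daily-dose package price."""
    per_day = []
    for pkg in packages:
        if pkg.ddd_count <= 0:
            raise ValueError("package must cover a positive number of daily doses")
        per_day.append(
            statutory_share * pkg.statutory_price / pkg.ddd_count
            + (1.0 - statutory_share) * pkg.private_price / pkg.ddd_count
        )
    return float(np.mean(per_day))


def cost_medication(
    packages: Sequence[MedicationPackage],
    days_supplied: float,
    statutory_share: float = 0.89,
) -> float:
    """Cost of ``days_supplied`` days of antidepressant use."""
    if days_supplied < 0:
        raise ValueError("days_supplied must be >= 0")
    return medication_per_day_price(packages, statutory_share) * days_supplied


# -- elementary valuations ----------------------------------------------------

def value_absenteeism(absent_days, gross_daily_wage):
    """Human-capital value of days not worked."""
    return np.asarray(absent_days, float) * np.asarray(gross_daily_wage, float)


def value_presenteeism(presenteeism_days, efficiency_rating, gross_daily_wage):
    """Value of reduced productivity while at work.

    ``efficiency_rating`` is the participant's 0-10 self-rated efficiency on
    affected days; a day at rating r costs (1 - r/10) of the gross daily wage.
    """
    rating = np.asarray(efficiency_rating, float)
    if np.any((rating < 0) | (rating > 10)):
        raise ValueError("efficiency rating must be in [0, 10]")
    days = np.asarray(presenteeism_days, float)
    return days * (1.0 - rating / 10.0) * np.asarray(gross_daily_wage, float)


def value_unpaid(hours, shadow_price: float = 18.33):
    """Shadow-price valuation of unpaid work (informal care, domestic help)."""
    return np.asarray(hours, float) * shadow_price


def cost_contacts(panel: Mapping[str, float], prices: UnitPriceTable) -> dict:
    """Price the unit-priced panel fields (contacts, inpatient days, day care,
    travel, unpaid hours) of one recall window; returns category -> €."""
    out: dict[str, float] = {}
    for fld, qty in panel.items():
        if fld not in FIELD_VALUATION:
            raise SchemaError(f"unknown resource-use field {fld!r}")
        cat, rule = FIELD_VALUATION[fld]
        if not rule.startswith("price:"):
            continue
        if qty < 0:
            raise ValueError(f"{fld}: quantity must be >= 0")
        out[cat] = out.get(cat, 0.0) + qty * getattr(prices, rule.split(":", 1)[1])
    return out


# -- cohort-level costing -----------------------------------------------------

def wave_costs(
    waves: pd.DataFrame,
    prices: UnitPriceTable,
    extrapolation_factor: float = 2.0,
    med_packages: Sequence[MedicationPackage] = DEFAULT_MEDICATION_PACKAGES,
) -> pd.DataFrame:
    """Cost every resource-use recall window of the costed waves.

    Returns one row per participant x costed wave with one € column per
    cost category (already extrapolated to the wave's 6-month interval).
    Missing quantities propagate as missing costs — imputation runs on this
    table before annual aggregation.
    """
    rows = waves[waves["wave"].isin(COST_WAVES)]
    out = rows[["pid", "arm", "wave"]].copy()
    med_pd = medication_per_day_price(med_packages, prices.statutory_share)
    cat_cols = {}
    for fld, (cat, rule) in FIELD_VALUATION.items():
        qty = rows[fld].to_numpy(float)
        if rule.startswith("price:"):
            cost = qty * getattr(prices, rule.split(":", 1)[1])
        elif rule == "euro":
            cost = qty
        elif rule == "medication":
            cost = qty * med_pd
        elif rule == "wage_absent":
            cost = value_absenteeism(qty, rows["gross_daily_wage"].to_numpy(float))
        elif rule == "wage_presenteeism":
            rating = rows["efficiency_rating"].to_numpy(float)
            # unrated windows with zero affected days cost nothing
            rating = np.where(np.isnan(rating) & (qty == 0), 10.0, rating)
            bad = (~np.isnan(rating)) & ((rating < 0) | (rating > 10))
            if bad.any():
                raise ValueError("efficiency rating must be in [0, 10]")
            wage = rows["gross_daily_wage"].to_numpy(float)
            cost = qty * (1.0 - rating / 10.0) * wage
        else:  # pragma: no cover
            raise SchemaError(rule)
        cat_cols.setdefault(cat, []).append(cost * extrapolation_factor)
    for cat, parts in cat_cols.items():
        out[cat] = np.sum(parts, axis=0)
    return out


def participant_costs(
    wave_cost_table: pd.DataFrame,
    participants: pd.DataFrame,
    prices: UnitPriceTable,
) -> pd.DataFrame:
    """Annual per-participant cost breakdown (€, one column per category).

    Sums the costed waves, adds the program cost of the assigned arm and the
    opportunity cost of participant time. Missing hospital-category wave
    costs contribute 0 (they are never imputed); any other category must be
    complete by this point.
    """
    cats = [c for c in CATEGORIES if c in wave_cost_table.columns]
    filled = wave_cost_table.copy()
    for cat in HOSPITAL_CATEGORIES:
        if cat in filled:
            filled[cat] = filled[cat].fillna(0.0)
    nonhosp = [c for c in cats if c not in HOSPITAL_CATEGORIES]
    if filled[nonhosp].isna().any().any():
        raise ValueError(
            "wave cost table has missing non-hospital categories; "
            "run imputation before aggregating annual costs")
    annual = filled.groupby("pid")[cats].sum(min_count=1).reset_index()
    out = participants[["pid", "arm"]].merge(annual, on="pid", how="left")
    for cat in cats:
        out[cat] = out[cat].fillna(0.0)
    out["intervention"] = np.where(
        out["arm"] == "intervention",
        prices.intervention_cost, prices.control_program_cost)
    hours = participants.set_index("pid")["intervention_hours"]
    out["opportunity_time"] = (
        out["pid"].map(hours).fillna(0.0) * prices.opportunity_cost)
    return out[["pid", "arm"] + list(CATEGORIES)]


def aggregate_costs(
    breakdown: Mapping[str, float] | pd.DataFrame,
    perspective: str,
    include_opportunity_cost: bool = False,
    drop_hospitalization: bool = False,
):
    """Total annual cost under a perspective.

    ``health_care`` counts direct medical costs (program, contacts,
    inpatient/day care, medication, copayments, OTC); ``societal``
    additionally counts patient/family costs and productivity losses.
    Participant time is a separate category excluded from both totals
    unless requested.
    """
    if perspective == "health_care":
        cats = list(HEALTH_CARE_CATEGORIES)
    elif perspective == "societal":
        cats = list(HEALTH_CARE_CATEGORIES) + list(SOCIETAL_ONLY_CATEGORIES)
    else:
        raise SchemaError(f"unknown perspective {perspective!r}")
    if include_opportunity_cost:
        cats.append("opportunity_time")
    if drop_hospitalization:
        cats = [c for c in cats if c not in HOSPITAL_CATEGORIES]
    if isinstance(breakdown, pd.DataFrame):
        return breakdown[cats].sum(axis=1)
    missing = [c for c in cats if c not in breakdown]
    if missing:
        raise SchemaError(f"breakdown missing categories: {missing}")
    return float(sum(breakdown[c] for c in cats))


def index_and_convert(amount, index_factor: float = 1.04,
                      rate: float = 0.85) -> tuple:
    """Index an amount to the reference price year and convert € to £.

    Returns (indexed €, converted £); display rounding is left to reporting.
    """
    amount = np.asarray(amount, float)
    if np.any(amount < 0):
        raise ValueError("amount must be >= 0")
    indexed = amount * index_factor
    return indexed, indexed * rate
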