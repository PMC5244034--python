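"""Price a single participant's resource use step by step.

Shows the unit-price costing of care contacts, the DDD-weighted medication
price, human-capital valuation of absenteeism and presenteeism, shadow-price
valuation of unpaid work, the two perspective totals, and conversion of €
amounts to £.
"""

from depcea.config import DEFAULT_MEDICATION_PACKAGES, UnitPriceTable
from depcea.costing import (
    aggregate_costs,
    cost_contacts,
    cost_medication,
    index_and_convert,
    value_absenteeism,
    value_presenteeism,
    value_unpaid,
)

prices = UnitPriceTable()

# one quarterly recall window of health care use
panel = {"gp_visits": 5, "psychotherapist_sessions": 2,
         "inpatient_mental_days": 0, "travel_km": 100,
         "informal_care_hours": 10}
contact_costs = cost_contacts(panel, prices)
for cat, eur in contact_costs.items():
    print(f"{cat:>16}: €{eur:8.2f}")
# 5 GP visits at €20.92 = €104.60; 100 km at €0.30/km = €30.00

med = cost_medication(DEFAULT_MEDICATION_PACKAGES, days_supplied=90)
print(f"antidepressants (90 days, statutory-weighted DDD price): €{med:.2f}")

absent = value_absenteeism(10, 100)
present = value_presenteeism(5, 6, 120)
print(f"absenteeism 10 days at €100/day gross wage: €{absent:.0f}")
print(f"presenteeism 5 days at efficiency 6/10, wage €120: €{present:.0f} "
      "(each day costs 40% of the wage)")
print(f"domestic help 10 h at the €18.33 shadow price: "
      f"€{value_unpaid(10):.2f}")

breakdown = {
    "intervention": 299, "gp_internist": 104.60, "mental_health": 162.88,
    "other_specialist": 0, "inpatient": 0, "daycare": 0,
    "antidepressants": med, "private_therapist": 0, "copayments": 12,
    "otc": 8, "informal_care": 183.30, "domestic_help": 183.30,
    "travel": 30, "absenteeism": absent, "presenteeism": present,
    "opportunity_time": 0,
}
hc = aggregate_costs(breakdown, "health_care")
soc = aggregate_costs(breakdown, "societal")
print(f"health care perspective total: €{hc:.0f} (direct medical costs only)")
print(f"societal perspective total:    €{soc:.0f} "
      "(adds patient/family costs and productivity losses)")

indexed, gbp = index_and_convert(soc, index_factor=1.0)
print(f"societal total in pound sterling: £{gbp:.0f} (at £0.85 per €)")
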