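"""Generate a synthetic two-arm prevention trial and inspect its structure.

The default configuration emulates a 406-participant trial of a web-based
guided self-help programme against enhanced usual care: exponential time to
onset of major depression calibrated to 43 vs 37 mean depression-free weeks,
baseline EQ-5D utility ~0.74 in both arms, zero-inflated right-skewed cost
categories and ~70% retention at 12 months (lower in the intervention arm).
"""

import numpy as np

from depcea import SyntheticTrialConfig, generate_cohort
from depcea.config import YEAR_DAYS

config = SyntheticTrialConfig()
cohort = generate_cohort(config, seed=1)

parts = cohort.participants
print(f"participants: {len(parts)} "
      f"({(parts.arm == 'intervention').sum()} intervention / "
      f"{(parts.arm == 'control').sum()} control)")

onset = parts["onset_day"].to_numpy()
weeks = np.where(np.isnan(onset), YEAR_DAYS, onset) / 7.0
for arm in ("intervention", "control"):
    m = (parts["arm"] == arm).to_numpy()
    print(f"{arm:>13}: mean depression-free weeks {weeks[m].mean():.1f}, "
          f"onsets {int(parts['event'][m].sum())}")

base = cohort.waves.query("wave == 0")
print(f"baseline EQ-5D utility: mean {base['eq5d'].mean():.3f} "
      f"(SD {base['eq5d'].std():.3f}) — balanced by design")

w3 = cohort.waves.query("wave == 3")
ret = w3.groupby("arm")["observed"].mean()
print(f"12-month retention: intervention {ret['intervention']:.1%}, "
      f"control {ret['control']:.1%} "
      "(differential dropout, missing at random given arm and severity)")
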