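"""Effect measures: depression-free years from onset timing and QALYs by
area under the linearly interpolated utility curve.

One depression-free year (DFY) is a full 12-month follow-up without onset of
major depression; a QALY of 1 is full health throughout the 12 months. No
baseline adjustment is applied (baseline utilities were balanced across arms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import N_WAVES, WAVE_TIMES, YEAR_DAYS


@dataclass
class OnsetReport:
    """Onset dating from the life-chart interview.

    ``anchor_day`` is the first day of the reported period (or the exact day
    at day granularity); midpoints are used when only the week or month of
    onset could be established.
    """

    granularity: str            # {"day", "week", "month"}
    anchor_day: float
    month_length: int = 30


def resolve_onset_day(report: OnsetReport,
                      horizon_days: float = YEAR_DAYS) -> float:
    """Resolve a dated onset report to a day index within follow-up."""
    if not 0 <= report.anchor_day <= horizon_days:
        raise ValueError("onset anchor outside the follow-up horizon")
    if report.granularity == "day":
        day = report.anchor_day
    elif report.granularity == "week":
        day = report.anchor_day + 3  # 4th day of the 7-day window
    elif report.granularity == "month":
        day = report.anchor_day + 15  # day 15 of the month window
    else:
        raise ValueError(f"unknown granularity {report.granularity!r}")
    return min(day, horizon_days)


def depression_free_years(onset_day, horizon_days: float = YEAR_DAYS):
    """DFY = min(onset, horizon)/365.25; censored (NaN) counts as a full year."""
    day = np.asarray(onset_day, float)
    if np.any(day[~np.isnan(day)] < 0):
        raise ValueError("onset day must be >= 0")
    dfy = np.where(np.isnan(day), 1.0, np.minimum(day, horizon_days) / horizon_days)
    return float(dfy) if np.isscalar(onset_day) else dfy


def qaly_auc(utilities, times=WAVE_TIMES) -> float:
    """Trapezoid-rule QALY over the follow-up year.

    All waves must be present (run imputation first); utilities at or below 1
    yield a QALY at or below the duration spanned by ``times``.
    """
    u = np.asarray(utilities, float)
    t = np.asarray(times, float)
    if u.shape[-1] != t.size:
        raise ValueError("one utility per assessment wave is required")
    if np.any(np.isnan(u)):
        raise ValueError("missing utility wave: run imputation before QALY AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("wave times must be strictly increasing")
    return np.trapezoid(u, t, axis=-1)


def compute_effects(cohort) -> pd.DataFrame:
    """Participant-level effect table: DFY, EQ-5D QALY, SF-6D QALY.

    Requires a completed cohort (all four utility waves present for both
    instruments, post-imputation).
    """
    parts = cohort.participants.sort_values("pid")
    waves = cohort.waves.sort_values(["pid", "wave"])
    n = len(parts)
    out = parts[["pid", "arm"]].copy()
    out["DFY"] = depression_free_years(parts["onset_day"].to_numpy())
    times = waves["time_years"].to_numpy()[:N_WAVES]
    for inst, col in (("EQ5D", "eq5d"), ("SF6D", "sf6d")):
        u = waves[col].to_numpy().reshape(n, N_WAVES)
        out[inst] = qaly_auc(u, times)
    return out


@dataclass
class EffectSummary:
    """Between-arm comparison of one effect measure (independent-samples t)."""

    effect: str
    mean_intervention: float
    sd_intervention: float
    mean_control: float
    sd_control: float
    difference: float
    ci_low: float
    ci_high: float
    t_statistic: float
    df: float
    p_value: float


def arm_effect_summary(effects: pd.DataFrame, effect: str,
                       alpha: float = 0.05) -> EffectSummary:
    """Pooled-variance two-sample t comparison of an effect between arms."""
    xi = effects.loc[effects["arm"] == "intervention", effect].to_numpy(float)
    xc = effects.loc[effects["arm"] == "control", effect].to_numpy(float)
    if len(xi) < 2 or len(xc) < 2:
        raise ValueError("each arm needs at least 2 participants")
    ni, nc = len(xi), len(xc)
    diff = xi.mean() - xc.mean()
    sp2 = ((ni - 1) * xi.var(ddof=1) + (nc - 1) * xc.var(ddof=1)) / (ni + nc - 2)
    se = np.sqrt(sp2 * (1 / ni + 1 / nc))
    df = ni + nc - 2
    t = diff / se if se > 0 else 0.0
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    p = 2 * stats.t.sf(abs(t), df)
    return EffectSummary(
        effect=effect,
        mean_intervention=xi.mean(), sd_intervention=xi.std(ddof=1),
        mean_control=xc.mean(), sd_control=xc.std(ddof=1),
        difference=diff, ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
        t_statistic=t, df=df, p_value=p)
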