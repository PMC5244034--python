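"""Time-to-onset analysis: Cox proportional hazards between arms (with
post-hoc covariate pruning) and restricted mean depression-free survival.

Times are weeks since randomization, administratively censored at the
12-month horizon (365.25/7 = 52.18 weeks). Ties are handled with Breslow's
approximation (week-resolution onset dating produces ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .config import WEEKS_PER_YEAR, YEAR_DAYS


def build_survival_records(participants: pd.DataFrame,
                           covariates: tuple = ()) -> pd.DataFrame:
    """Per-participant (time, event) records in weeks from onset days."""
    onset = participants["onset_day"].to_numpy(float)
    time = np.where(np.isnan(onset), YEAR_DAYS, np.minimum(onset, YEAR_DAYS)) / 7.0
    df = pd.DataFrame({
        "time_weeks": np.maximum(time, 1e-9),
        "event": participants["event"].to_numpy(bool),
        "treatment": (participants["arm"] == "intervention").astype(int),
    })
    for cov in covariates:
        df[cov] = pd.to_numeric(participants[cov]).to_numpy()
    return df


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    pruned: list = field(default_factory=list)
    summary: pd.DataFrame | None = None


def fit_cox(records: pd.DataFrame, covariates: tuple = (),
            alpha: float = 0.05) -> CoxResult:
    """Cox PH fit of time to onset on treatment, with covariate pruning.

    Covariates are entered post hoc; any covariate whose coefficient is
    non-significant (p >= alpha) is dropped and the model is refit on
    treatment alone.
    """
    if records["event"].sum() == 0:
        raise ValueError("no onset events: Cox model is inestimable")
    if records["treatment"].nunique() < 2:
        raise ValueError("both arms are required")

    def _fit(cols):
        cph = CoxPHFitter()
        cph.fit(records[["time_weeks", "event", *cols]],
                duration_col="time_weeks", event_col="event")
        return cph

    cols = ["treatment", *covariates]
    cph = _fit(cols)
    pruned = [c for c in covariates if cph.summary.loc[c, "p"] >= alpha]
    if pruned:
        kept = [c for c in cols if c not in pruned]
        cph = _fit(kept)
    row = cph.summary.loc["treatment"]
    return CoxResult(
        hazard_ratio=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p_value=float(row["p"]),
        pruned=pruned,
        summary=cph.summary,
    )


def _km_rmst(times: np.ndarray, events: np.ndarray,
             horizon: float) -> tuple:
    """Area under the Kaplan-Meier curve up to ``horizon`` and its
    Greenwood-type variance (sum over event times of the squared remaining
    area times d/(n(n-d)))."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_["KM_estimate"]
    t = sf.index.to_numpy(float)   # breakpoints, starting at 0
    s = sf.to_numpy(float)         # S on [t_k, t_{k+1})
    below = t < horizon
    tt = np.append(t[below], horizon)
    ss = s[below]
    seg = np.diff(tt) * ss
    # suffix[k] = integral of S from tt[k] to horizon
    suffix = np.append(np.cumsum(seg[::-1])[::-1], 0.0)
    mean = float(suffix[0] + (tt[0] if tt.size else horizon))
    table = kmf.event_table
    et = table.index.to_numpy(float)
    d = table["observed"].to_numpy(float)
    n_at_risk = table["at_risk"].to_numpy(float)
    valid = (d > 0) & (et < horizon) & (n_at_risk > d)
    idx = np.searchsorted(tt, et[valid])
    area_after = suffix[np.clip(idx, 0, suffix.size - 1)]
    dv, nv = d[valid], n_at_risk[valid]
    var = float(np.sum(area_after ** 2 * dv / (nv * (nv - dv))))
    return mean, var


def restricted_mean_survival(records: pd.DataFrame,
                             horizon_weeks: float = WEEKS_PER_YEAR,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Per-arm restricted mean depression-free weeks (area under the
    Kaplan-Meier curve up to the horizon) with Greenwood-based CIs."""
    from scipy.stats import norm

    rows = []
    zcrit = norm.ppf(1 - alpha / 2)
    for arm_label, treat in (("intervention", 1), ("control", 0)):
        sub = records[records["treatment"] == treat]
        if len(sub) == 0:
            raise ValueError(f"empty arm: {arm_label}")
        mean, var = _km_rmst(sub["time_weeks"].to_numpy(float),
                             sub["event"].to_numpy(bool), horizon_weeks)
        se = float(np.sqrt(max(var, 0.0)))
        rows.append({
            "arm": arm_label,
            "mean_weeks": float(mean),
            "ci_low": float(mean) - zcrit * se,
            "ci_high": float(mean) + zcrit * se,
            "n": len(sub),
            "events": int(sub["event"].sum()),
        })
    return pd.DataFrame(rows)
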