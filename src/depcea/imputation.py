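"""Regression imputation of missing cost and utility values.

Missing wave-specific category costs and wave utilities are replaced by
conditional means from linear models whose predictors are baseline variables
screened for association with the outcome (linear regression) and with
dropout (logistic regression on the wave's missingness indicator). Retention
uses a univariable screen at p < alpha followed by a joint fit. Hospital
cost categories are never imputed: too few admissions occur for a stable
model, so missing hospital costs contribute zero and are instead probed in a
sensitivity analysis. Observed values are never altered, which makes the
procedure idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import COST_WAVES, N_WAVES, UnitPriceTable
from .cohort import Cohort
from .costing import CATEGORIES, HOSPITAL_CATEGORIES, wave_costs

DEFAULT_CANDIDATES = (
    "treatment", "age", "female", "employed",
    "baseline_symptoms", "baseline_eq5d", "baseline_sf6d",
)


@dataclass
class ImputationModel:
    """Fitted conditional-mean model for one imputation target."""

    target: str
    predictors: list
    params: pd.Series
    n_observed: int
    n_missing: int
    screen: pd.DataFrame = field(default=None, repr=False)


def select_predictors(frame: pd.DataFrame, candidates, target: str,
                      mode: str, alpha: float = 0.05):
    """Univariable screen: retain candidates with slope p < alpha.

    ``outcome`` mode regresses the observed target values on each candidate
    (OLS); ``dropout`` mode fits a logistic regression of the binary
    missingness indicator on each candidate. Returns (retained, screen table).
    """
    if mode not in ("outcome", "dropout"):
        raise ValueError(f"unknown selection mode {mode!r}")
    y_all = frame[target]
    rows = []
    retained = []
    for cand in candidates:
        x_all = pd.to_numeric(frame[cand])
        if x_all.isna().any():
            raise ValueError(
                f"candidate {cand!r} has missing values; predictors must be "
                "fully observed baseline variables")
        if mode == "outcome":
            keep = y_all.notna()
            y, x = y_all[keep].astype(float), x_all[keep]
        else:
            if y_all.isna().any():
                raise ValueError("dropout indicator must be fully observed")
            y, x = y_all.astype(float), x_all
        p = np.nan
        if x.nunique() > 1 and y.nunique() > 1 and len(y) > 3:
            X = sm.add_constant(x.to_numpy(float))
            try:
                if mode == "outcome":
                    fit = sm.OLS(y.to_numpy(), X).fit()
                else:
                    fit = sm.Logit(y.to_numpy(), X).fit(disp=0, maxiter=200)
                p = float(fit.pvalues[1])
            except Exception:
                p = np.nan
        keep_it = bool(p < alpha) if np.isfinite(p) else False
        rows.append({"candidate": cand, "mode": mode, "p_value": p,
                     "retained": keep_it})
        if keep_it:
            retained.append(cand)
    return retained, pd.DataFrame(rows)


def fit_imputation_model(frame: pd.DataFrame, target: str, predictors,
                         screen: pd.DataFrame | None = None) -> ImputationModel:
    """Joint OLS fit of the target on the retained predictors (plus intercept)."""
    obs = frame[target].notna()
    if obs.sum() < max(2, len(predictors) + 1):
        raise ValueError(f"too few observed values to impute {target!r}")
    X = frame.loc[obs, list(predictors)].apply(pd.to_numeric).to_numpy(float)
    X = np.column_stack([np.ones(obs.sum()), X])
    beta, *_ = np.linalg.lstsq(X, frame.loc[obs, target].to_numpy(float),
                               rcond=None)
    params = pd.Series(beta, index=["const", *predictors])
    return ImputationModel(target=target, predictors=list(predictors),
                           params=params, n_observed=int(obs.sum()),
                           n_missing=int((~obs).sum()), screen=screen)


def impute_conditional_mean(frame: pd.DataFrame,
                            models: list[ImputationModel]) -> pd.DataFrame:
    """Replace missing target values by model predictions.

    Observed values are never altered; a second pass is a no-op.
    """
    out = frame.copy()
    for model in models:
        miss = out[model.target].isna()
        if not miss.any():
            continue
        Xm = out.loc[miss, model.predictors].apply(pd.to_numeric)
        if Xm.isna().any().any():
            raise ValueError(
                f"imputing {model.target!r} requires missing predictors; "
                "impute predictors first")
        X = np.column_stack([np.ones(miss.sum()), Xm.to_numpy(float)])
        out.loc[miss, model.target] = X @ model.params.to_numpy()
    return out


def _wide_frame(cohort: Cohort, cost_table: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: baseline candidates, per-wave targets,
    per-wave missingness indicators."""
    parts = cohort.participants.sort_values("pid").reset_index(drop=True)
    waves = cohort.waves.sort_values(["pid", "wave"])
    frame = pd.DataFrame({
        "pid": parts["pid"],
        "treatment": (parts["arm"] == "intervention").astype(int),
        "age": parts["age"].astype(float),
        "female": (parts["sex"] == "female").astype(int),
        "employed": parts["employed"].astype(int),
        "baseline_symptoms": parts["baseline_symptoms"].astype(float),
    })
    n = len(parts)
    for inst, col in (("eq5d", "eq5d"), ("sf6d", "sf6d")):
        u = waves[col].to_numpy().reshape(n, N_WAVES)
        frame[f"baseline_{inst}"] = u[:, 0]
        for w in range(1, N_WAVES):
            frame[f"{inst}_w{w}"] = u[:, w]
    obs = waves["observed"].to_numpy().reshape(n, N_WAVES)
    for w in range(1, N_WAVES):
        frame[f"missing_w{w}"] = (~obs[:, w]).astype(int)
    cost_cats = [c for c in CATEGORIES
                 if c in cost_table.columns and c not in HOSPITAL_CATEGORIES]
    for w in COST_WAVES:
        sub = cost_table[cost_table["wave"] == w].set_index("pid")
        for cat in cost_cats:
            frame[f"cost_{cat}_w{w}"] = frame["pid"].map(sub[cat])
    return frame


@dataclass
class CompletedCohort:
    """Imputation output: completed utilities/waves, completed wave-level
    category costs, the fitted models and an audit table."""

    cohort: Cohort
    wave_costs: pd.DataFrame
    models: list
    audit: pd.DataFrame

    def write_audit(self, path) -> None:
        self.audit.to_csv(path, index=False)


def impute_cohort(cohort: Cohort,
                  prices: UnitPriceTable | None = None,
                  extrapolation_factor: float = 2.0,
                  alpha: float = 0.05,
                  candidates=DEFAULT_CANDIDATES) -> CompletedCohort:
    """Full imputation pass over a cohort.

    Order: cost the observed recall windows, screen dropout predictors per
    wave, screen outcome predictors per target, fit the joint models, then
    predict the missing values. Returns the completed cohort plus an audit
    of every selection decision and fitted coefficient.
    """
    prices = prices or UnitPriceTable()
    cost_table = wave_costs(cohort.waves, prices, extrapolation_factor)
    frame = _wide_frame(cohort, cost_table)

    dropout_sets: dict[int, tuple] = {}
    audit_rows = []
    for w in range(1, N_WAVES):
        if frame[f"missing_w{w}"].nunique() > 1:
            kept, screen = select_predictors(
                frame, candidates, f"missing_w{w}", "dropout", alpha)
        else:
            kept, screen = [], pd.DataFrame()
        dropout_sets[w] = tuple(kept)

    targets = []
    for inst in ("eq5d", "sf6d"):
        targets += [(f"{inst}_w{w}", w) for w in range(1, N_WAVES)]
    cost_cats = [c for c in CATEGORIES
                 if c in cost_table.columns and c not in HOSPITAL_CATEGORIES]
    for w in COST_WAVES:
        targets += [(f"cost_{cat}_w{w}", w) for cat in cost_cats]

    models = []
    for target, w in targets:
        if not frame[target].isna().any():
            audit_rows.append({"target": target, "n_observed":
                               int(frame[target].notna().sum()),
                               "n_imputed": 0, "predictors": "",
                               "coefficients": ""})
            continue
        outcome_kept, screen = select_predictors(
            frame, candidates, target, "outcome", alpha)
        union = list(dict.fromkeys([*outcome_kept, *dropout_sets[w]]))
        model = fit_imputation_model(frame, target, union, screen)
        models.append(model)
        audit_rows.append({
            "target": target,
            "n_observed": model.n_observed,
            "n_imputed": model.n_missing,
            "predictors": ";".join(model.predictors),
            "coefficients": ";".join(
                f"{k}={v:.6g}" for k, v in model.params.items()),
        })

    completed = impute_conditional_mean(frame, models)

    waves = cohort.waves.sort_values(["pid", "wave"]).reset_index(drop=True)
    n = len(cohort.participants)
    for inst, col in (("eq5d", "eq5d"), ("sf6d", "sf6d")):
        for w in range(1, N_WAVES):
            idx = waves.index[waves["wave"] == w]
            vals = completed[f"{inst}_w{w}"].to_numpy()
            waves.loc[idx, col] = vals
    new_costs = cost_table.copy()
    for w in COST_WAVES:
        idx = new_costs.index[new_costs["wave"] == w]
        pid_order = new_costs.loc[idx, "pid"]
        lookup = completed.set_index("pid")
        for cat in cost_cats:
            new_costs.loc[idx, cat] = pid_order.map(
                lookup[f"cost_{cat}_w{w}"]).to_numpy()
    return CompletedCohort(
        cohort=Cohort(cohort.participants.copy(), waves),
        wave_costs=new_costs,
        models=models,
        audit=pd.DataFrame(audit_rows),
    )
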