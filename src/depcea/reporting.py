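"""Pipeline orchestration and report rendering.

``run_pipeline`` drives simulate → cost → impute → effects → CEA → export and
writes every artifact as CSV (cost table, CEA summary table, CEAC curves,
cost-effectiveness-plane scatters, imputation audit, survival summary) plus a
plain-text run log. Display conventions: whole € for costs and ICERs, two
decimals for effects, whole percent for quadrant shares.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import IncrementalResult, ceac, evaluate
from .cohort import Cohort, generate_cohort
from .config import AnalysisConfig, SyntheticTrialConfig, UnitPriceTable
from .costing import (
    CATEGORIES,
    HOSPITAL_CATEGORIES,
    aggregate_costs,
    index_and_convert,
    participant_costs,
)
from .imputation import CompletedCohort, impute_cohort
from .outcomes import compute_effects
from .survival import build_survival_records, fit_cox, restricted_mean_survival

UNDEFINED_CI_MARKER = "no dependably accurate 95% CI (no ray through the origin excludes alpha/2)"


def format_percent(numerator: float, denominator: float) -> str:
    """Share rendered to one decimal, e.g. 286/406 -> '70.4%'."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    return f"{100.0 * numerator / denominator:.1f}%"


def round_euro(amount: float) -> int:
    """Display rounding of € amounts to whole units (half away from zero)."""
    return int(np.floor(amount + 0.5)) if amount >= 0 else -int(
        np.floor(-amount + 0.5))


@dataclass
class VariantResult:
    """One analysis × perspective × effect block of the CEA table."""

    analysis: str        # "main" or "no_hospitalization"
    perspective: str
    effect: str
    result: IncrementalResult
    ceac: "pd.DataFrame"


@dataclass
class ReportBundle:
    cohort: Cohort
    completed: CompletedCohort
    breakdown: pd.DataFrame
    effects: pd.DataFrame
    cost_table: pd.DataFrame
    cea_table: pd.DataFrame
    variants: list = field(default_factory=list)
    survival_summary: pd.DataFrame | None = None
    cox: object | None = None


def build_cost_table(breakdown: pd.DataFrame,
                     include_opportunity_cost: bool = False) -> pd.DataFrame:
    """Per-category arm means and SDs with the incremental column, plus the
    perspective totals, mirroring the annual-cost report layout."""
    rows = []
    bi = breakdown[breakdown["arm"] == "intervention"]
    bc = breakdown[breakdown["arm"] == "control"]

    def add(label, vi, vc):
        rows.append({
            "category": label,
            "mean_intervention": vi.mean(), "sd_intervention": vi.std(ddof=1),
            "mean_control": vc.mean(), "sd_control": vc.std(ddof=1),
            "incremental": vi.mean() - vc.mean(),
        })

    for cat in CATEGORIES:
        if cat == "opportunity_time" and not include_opportunity_cost:
            continue
        add(cat, bi[cat], bc[cat])
    for persp in ("health_care", "societal"):
        ti = aggregate_costs(bi, persp, include_opportunity_cost)
        tc = aggregate_costs(bc, persp, include_opportunity_cost)
        add(f"total_{persp}", ti, tc)
    table = pd.DataFrame(rows)
    for col in ("mean_intervention", "mean_control", "incremental"):
        _, gbp = index_and_convert(np.abs(table[col].to_numpy()),
                                   index_factor=1.0)
        table[col + "_gbp"] = np.sign(table[col].to_numpy()) * gbp
    return table


def analyze_variants(breakdown: pd.DataFrame, effects: pd.DataFrame,
                     config: AnalysisConfig,
                     seed: int | None = None) -> list:
    """Run the bootstrap CEA for every configured variant.

    Variant grid: main analysis over perspectives × effects (plus the SF-6D
    sensitivity effect), and the no-hospitalization sensitivity over the
    primary effects. Each variant draws an independent reproducible seed
    stream from the master seed.
    """
    config.validate()
    master = config.seed if seed is None else seed
    data = breakdown.merge(effects[["pid", "DFY", "EQ5D", "SF6D"]], on="pid")
    arm = (data["arm"] == "intervention").astype(float).to_numpy()
    grid = []
    for persp in config.perspectives:
        for eff in config.variant_effects():
            grid.append(("main", persp, eff))
    if config.drop_hospitalization:
        for persp in config.perspectives:
            for eff in config.effects:
                grid.append(("no_hospitalization", persp, eff))
    streams = np.random.SeedSequence(master).spawn(len(grid))
    out = []
    for (analysis, persp, eff), ss in zip(grid, streams):
        costs = aggregate_costs(
            data, persp,
            include_opportunity_cost=config.include_opportunity_cost,
            drop_hospitalization=(analysis == "no_hospitalization"),
        ).to_numpy()
        res = evaluate(costs, data[eff].to_numpy(), arm,
                       B=config.n_bootstrap,
                       seed=np.random.default_rng(ss))
        curve = ceac(res.distribution, config.lambda_grid)
        out.append(VariantResult(analysis, persp, eff, res, curve.to_frame()))
    return out


def _round_shares_to_percent(quadrants: dict) -> dict:
    """Largest-remainder rounding so the four shares total exactly 100%."""
    raw = {k: 100.0 * v for k, v in quadrants.items()}
    floors = {k: int(np.floor(v)) for k, v in raw.items()}
    short = 100 - sum(floors.values())
    order = sorted(raw, key=lambda k: raw[k] - floors[k], reverse=True)
    for k in order[:short]:
        floors[k] += 1
    return floors


def build_cea_table(variants: list) -> pd.DataFrame:
    """CEA summary table: one row per analysis × perspective × effect."""
    rows = []
    for v in variants:
        r = v.result
        und = r.ci_icer is None
        rows.append({
            "analysis": v.analysis,
            "perspective": v.perspective,
            "effect": v.effect,
            "delta_cost": round_euro(r.delta_cost),
            "ci_cost_low": round_euro(r.ci_cost[0]),
            "ci_cost_high": round_euro(r.ci_cost[1]),
            "delta_effect": round(r.delta_effect, 2),
            "ci_effect_low": round(r.ci_effect[0], 2),
            "ci_effect_high": round(r.ci_effect[1], 2),
            "icer": (round_euro(r.icer) if r.icer is not None else np.nan),
            "icer_ci_low": (np.nan if und else round_euro(r.ci_icer[0])),
            "icer_ci_high": (np.nan if und else round_euro(r.ci_icer[1])),
            "icer_ci_undefined": und,
        })
        shares = _round_shares_to_percent(r.quadrants)
        rows[-1].update({f"share_{q.lower()}_pct": shares[q]
                         for q in ("NE", "NW", "SE", "SW")})
    return pd.DataFrame(rows)


def render_cea_table(table: pd.DataFrame) -> str:
    """Human-readable rendering; undefined ICER CIs carry a footnote marker."""
    lines = []
    for _, row in table.iterrows():
        if row["icer_ci_undefined"]:
            ci = "^d"
        else:
            ci = f" ({row['icer_ci_low']:.0f} to {row['icer_ci_high']:.0f})"
        icer_txt = ("undefined" if pd.isna(row["icer"])
                    else f"{row['icer']:.0f}{ci}")
        lines.append(
            f"{row['analysis']}/{row['perspective']}/{row['effect']}: "
            f"dC {row['delta_cost']:.0f} "
            f"({row['ci_cost_low']:.0f} to {row['ci_cost_high']:.0f}), "
            f"dE {row['delta_effect']:.2f} "
            f"({row['ci_effect_low']:.2f} to {row['ci_effect_high']:.2f}), "
            f"ICER {icer_txt}, "
            f"NE/NW/SE/SW {row['share_ne_pct']:.0f}/{row['share_nw_pct']:.0f}"
            f"/{row['share_se_pct']:.0f}/{row['share_sw_pct']:.0f}%")
    if table["icer_ci_undefined"].any():
        lines.append("^d " + UNDEFINED_CI_MARKER)
    return "\n".join(lines)


def run_pipeline(synth_config: SyntheticTrialConfig | None = None,
                 analysis_config: AnalysisConfig | None = None,
                 prices: UnitPriceTable | None = None,
                 cohort: Cohort | None = None,
                 outdir=None,
                 log=sys.stderr) -> ReportBundle:
    """Full pipeline: simulate (or take a cohort), cost, impute, compute
    effects, run the survival and bootstrap CEA analyses, export artifacts."""
    analysis_config = analysis_config or AnalysisConfig()
    analysis_config.validate()
    prices = prices or UnitPriceTable()
    prices.validate()

    def say(msg):
        if log is not None:
            print(msg, file=log)

    if cohort is None:
        synth_config = synth_config or SyntheticTrialConfig()
        cohort = generate_cohort(synth_config, prices=prices)
        say(f"depcea {__version__}: simulated cohort "
            f"n={len(cohort.participants)} (seed={synth_config.seed})")
    else:
        say(f"depcea {__version__}: loaded cohort n={len(cohort.participants)}")

    completed = impute_cohort(
        cohort, prices,
        extrapolation_factor=analysis_config.extrapolation_factor)
    breakdown = participant_costs(
        completed.wave_costs, cohort.participants, prices)
    effects = compute_effects(completed.cohort)
    effects = effects.rename(columns={"EQ5D": "EQ5D", "SF6D": "SF6D"})

    cost_table = build_cost_table(
        breakdown, analysis_config.include_opportunity_cost)
    variants = analyze_variants(breakdown, effects, analysis_config)
    cea_table = build_cea_table(variants)

    records = build_survival_records(
        cohort.participants,
        covariates=("antidepressant_use",)
        if "antidepressant_use" in cohort.participants else ())
    surv = restricted_mean_survival(records)
    cox = None
    if records["event"].sum() > 0:
        cox = fit_cox(records, covariates=tuple(
            c for c in ("antidepressant_use",) if c in records))

    say(f"analysis seed={analysis_config.seed}, "
        f"B={analysis_config.n_bootstrap}, variants={len(variants)}")

    bundle = ReportBundle(
        cohort=cohort, completed=completed, breakdown=breakdown,
        effects=effects, cost_table=cost_table, cea_table=cea_table,
        variants=variants, survival_summary=surv, cox=cox)
    if outdir is not None:
        write_bundle(bundle, outdir, analysis_config)
    return bundle


def write_bundle(bundle: ReportBundle, outdir,
                 analysis_config: AnalysisConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.cohort.write_csv(outdir)
    effects_out = bundle.cohort.participants.merge(
        bundle.effects.rename(columns={"EQ5D": "EQ5D_QALY",
                                       "SF6D": "SF6D_QALY"}),
        on=["pid", "arm"])
    effects_out.to_csv(outdir / "participants_effects.csv", index=False)
    bundle.breakdown.to_csv(outdir / "participant_costs.csv", index=False)
    bundle.cost_table.to_csv(outdir / "cost_table.csv", index=False)
    bundle.cea_table.to_csv(outdir / "cea_table.csv", index=False)
    bundle.completed.audit.to_csv(outdir / "imputation_audit.csv", index=False)
    if bundle.survival_summary is not None:
        bundle.survival_summary.to_csv(outdir / "survival_summary.csv",
                                       index=False)
    for v in bundle.variants:
        tag = f"{v.analysis}_{v.perspective}_{v.effect}"
        v.ceac.to_csv(outdir / f"ceac_{tag}.csv", index=False)
        v.result.distribution.to_frame().to_csv(
            outdir / f"scatter_{tag}.csv", index=False)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"depcea {__version__}\n")
        fh.write(f"analysis_seed={analysis_config.seed}\n")
        fh.write(f"n_bootstrap={analysis_config.n_bootstrap}\n")
        fh.write(f"n_participants={len(bundle.cohort.participants)}\n")
        fh.write(render_cea_table(bundle.cea_table) + "\n")
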