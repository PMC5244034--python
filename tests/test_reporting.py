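"""Pipeline orchestration, report tables, rounding rules, determinism."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from depcea import SyntheticTrialConfig, format_percent, round_euro, run_pipeline
from depcea.cea import evaluate
from depcea.cohort import Cohort
from depcea.config import AnalysisConfig
from depcea.reporting import (
    UNDEFINED_CI_MARKER,
    build_cea_table,
    build_cost_table,
    render_cea_table,
    VariantResult,
)


def _small_configs(seed=0, analysis_seed=1):
    scfg = SyntheticTrialConfig()
    scfg.n_intervention = scfg.n_control = 60
    scfg.seed = seed
    acfg = AnalysisConfig(n_bootstrap=100, seed=analysis_seed,
                          lambda_grid=tuple(np.arange(0, 20001, 1000.0)))
    return scfg, acfg


def test_display_rounding_rules():
    assert format_percent(138, 202) == "68.3%"
    assert format_percent(286, 406) == "70.4%"
    assert round_euro(1116.67) == 1117
    assert round_euro(-827.5) == -828
    with pytest.raises(ValueError):
        format_percent(1, 0)


def test_build_cost_table_hand_computed(toy_breakdown):
    table = build_cost_table(toy_breakdown).set_index("category")
    row = table.loc["gp_internist"]
    assert row["mean_intervention"] == pytest.approx(150)
    assert row["sd_intervention"] == pytest.approx(np.std([100, 200], ddof=1))
    assert row["mean_control"] == pytest.approx(100)
    assert row["incremental"] == pytest.approx(50)
    assert table.loc["intervention", "incremental"] == pytest.approx(289)
    # totals equal the category sums under each perspective
    hc = table.loc["total_health_care"]
    assert hc["mean_intervention"] == pytest.approx(
        np.mean([299 + 100 + 0 + 0 + 0 + 0 + 10 + 5 + 0,
                 299 + 200 + 80 + 0 + 400 + 0 + 0 + 5 + 10]))
    soc = table.loc["total_societal"]
    assert soc["mean_intervention"] >= hc["mean_intervention"]
    # £ columns follow the configured conversion rate
    assert row["incremental_gbp"] == pytest.approx(50 * 0.85)


def test_build_cost_table_identical_arms(toy_breakdown):
    swapped = toy_breakdown.copy()
    swapped["arm"] = ["intervention", "control"] * 2
    swapped.loc[:, swapped.columns.difference(["pid", "arm"])] = 100.0
    table = build_cost_table(swapped)
    assert np.allclose(table["incremental"], 0.0)


def test_build_cea_table_passthrough_and_shares(rng):
    n = 300
    arm = (np.arange(n) % 2).astype(float)
    costs = 500 + 200 * arm + rng.gamma(1, 400, n)
    eff = 0.7 + 0.1 * arm + rng.normal(0, 0.1, n)
    res = evaluate(costs, eff, arm, B=400, seed=0)
    variant = VariantResult("main", "societal", "DFY", res,
                            pd.DataFrame({"wtp": [0], "probability": [0.5]}))
    table = build_cea_table([variant])
    row = table.iloc[0]
    assert row["delta_cost"] == round_euro(res.delta_cost)
    assert row["delta_effect"] == round(res.delta_effect, 2)
    assert row["icer"] == round_euro(res.icer)
    shares = row[["share_ne_pct", "share_nw_pct", "share_se_pct",
                  "share_sw_pct"]].sum()
    assert shares == 100


def test_cea_table_marks_undefined_ci(rng):
    from depcea.cea import (BootstrapDistribution, IncrementalResult,
                            icer_percentile_ci, percentile_ci, quadrant_shares)

    de = rng.normal(0, 0.05, 500)  # effect difference straddles zero
    dc = rng.normal(100, 60, 500)
    dist = BootstrapDistribution(de, dc, seed=None)
    ci_icer = icer_percentile_ci(dist)
    assert ci_icer is None
    res = IncrementalResult(
        delta_cost=float(dc.mean()), delta_effect=float(de.mean()),
        icer=float(dc.mean() / de.mean()),
        ci_cost=percentile_ci(dc), ci_effect=percentile_ci(de),
        ci_icer=ci_icer, quadrants=quadrant_shares(dist),
        residual_correlation=0.0, distribution=dist)
    table = build_cea_table([VariantResult("main", "societal", "EQ5D", res,
                                           pd.DataFrame())])
    assert bool(table.iloc[0]["icer_ci_undefined"])
    assert UNDEFINED_CI_MARKER in render_cea_table(table)


def test_run_pipeline_outputs_and_schemas(tmp_path):
    scfg, acfg = _small_configs()
    bundle = run_pipeline(scfg, acfg, outdir=tmp_path, log=None)
    for name in ("participants.csv", "waves.csv", "cost_table.csv",
                 "cea_table.csv", "participant_costs.csv",
                 "participants_effects.csv", "imputation_audit.csv",
                 "survival_summary.csv", "run_log.txt"):
        assert (tmp_path / name).exists(), name
    cea = pd.read_csv(tmp_path / "cea_table.csv")
    expected_rows = 2 * 3 + 2 * 2  # main: persp x (DFY, EQ5D, SF6D); no-hosp: persp x 2
    assert len(cea) == expected_rows
    shares = cea[["share_ne_pct", "share_nw_pct", "share_se_pct",
                  "share_sw_pct"]].sum(axis=1)
    assert (shares == 100).all()
    eff = pd.read_csv(tmp_path / "participants_effects.csv")
    assert {"DFY", "EQ5D_QALY", "SF6D_QALY"} <= set(eff.columns)
    # every variant exports a CEAC and a scatter
    for v in bundle.variants:
        tag = f"{v.analysis}_{v.perspective}_{v.effect}"
        assert (tmp_path / f"ceac_{tag}.csv").exists()
        scatter = pd.read_csv(tmp_path / f"scatter_{tag}.csv")
        assert len(scatter) == acfg.n_bootstrap


def test_drop_hospitalization_variant_excludes_hospital_costs(tmp_path):
    scfg, acfg = _small_configs()
    bundle = run_pipeline(scfg, acfg, outdir=None, log=None)
    from depcea.costing import aggregate_costs

    bd = bundle.breakdown
    with_h = aggregate_costs(bd, "health_care")
    without = aggregate_costs(bd, "health_care", drop_hospitalization=True)
    np.testing.assert_allclose(
        with_h - without, bd["inpatient"] + bd["daycare"], atol=1e-9)


def test_rerun_same_seed_is_byte_identical(tmp_path):
    scfg, acfg = _small_configs()
    run_pipeline(scfg, acfg, outdir=tmp_path / "a", log=None)
    scfg2, acfg2 = _small_configs()
    run_pipeline(scfg2, acfg2, outdir=tmp_path / "b", log=None)
    for f in sorted((tmp_path / "a").iterdir()):
        assert filecmp.cmp(f, tmp_path / "b" / f.name, shallow=False), f.name


def test_cohort_round_trip_reproduces_analysis(tmp_path):
    scfg, acfg = _small_configs()
    bundle = run_pipeline(scfg, acfg, outdir=tmp_path / "direct", log=None)
    cohort = Cohort.read_csv(tmp_path / "direct")
    bundle2 = run_pipeline(None, acfg, cohort=cohort,
                           outdir=tmp_path / "reloaded", log=None)
    pd.testing.assert_frame_equal(bundle.cea_table, bundle2.cea_table)
    pd.testing.assert_frame_equal(bundle.cost_table, bundle2.cost_table)


def test_cli_smoke(tmp_path):
    from click.testing import CliRunner

    from depcea.cli import main

    runner = CliRunner()
    scfg, _ = _small_configs()
    cfg_path = tmp_path / "scfg.yaml"
    scfg.to_yaml(cfg_path)
    r = runner.invoke(main, ["simulate", "--config", str(cfg_path),
                             "--out", str(tmp_path / "cohort")])
    assert r.exit_code == 0, r.output
    r = runner.invoke(main, ["cost", "--cohort", str(tmp_path / "cohort"),
                             "--out", str(tmp_path / "costs.csv")])
    assert r.exit_code == 0, r.output
    assert (tmp_path / "costs.csv").exists()
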