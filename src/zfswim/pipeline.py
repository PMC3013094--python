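"""End-to-end driver: respirometry → U_crit → economy → growth → expression.

Stages run in the experimental order and each is skipped when its input is
absent from the configuration.  Outputs are tidy CSVs plus a single
``summary.json`` of the derived headline quantities; given identical inputs
and seed the JSON is byte-identical across runs (all stages are
deterministic, keys are sorted, floats use repr round-tripping).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as zio
from .metabolic_model import (
    MetabolicPoint,
    analyze_fish,
    find_uopt,
    fit_cot_curve,
    fit_vo2_curve,
    cot_from_vo2,
    summarize_group,
)
from .qpcr import analyze_expression, expression_table
from .respirometry import fit_decline, mo2
from .growth_stats import run_growth_battery
from .swim_performance import ucrit_from_events

__all__ = ["run_pipeline"]

#: speeds below this fraction of U_crit are treated as the routine-activity
#: (RMR) condition and excluded from the metabolic curve fit
RMR_SPEED_CUTOFF_PCT = 10.0


def _respirometry_stage(config: zio.RunConfig, fish_records) -> pd.DataFrame:
    traces = zio.read_trace_csv(config.traces_csv)
    tunnel = config.tunnel
    rows = []
    for tr in traces:
        fish = fish_records.get(tr.fish_id)
        if fish is None or fish.body_weight_g is None:
            raise zio.ConfigError(f"no body mass on record for fish {tr.fish_id}")
        fit = fit_decline(tr, tunnel, min_r_squared=config.min_r_squared)
        rows.append(
            {
                "fish_id": tr.fish_id,
                "speed_pct_ucrit": tr.speed_pct_ucrit,
                "slope_umol_l_h": fit.slope_umol_l_h,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "mo2_umol_g_h": mo2(fit, tunnel, fish.body_weight_g),
            }
        )
    return pd.DataFrame(rows)


def _economy_stage(
    config: zio.RunConfig,
    points_df: pd.DataFrame,
    ucrit_by_fish: dict[str, float],
    fish_records,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    results = []
    for fish_id, sub in points_df.groupby("fish_id", sort=True):
        fish_id = str(fish_id)
        if fish_id not in ucrit_by_fish:
            continue
        rmr_rows = sub[sub["speed_pct_ucrit"] < RMR_SPEED_CUTOFF_PCT]
        rmr = float(rmr_rows["mo2_umol_g_h"].mean()) if len(rmr_rows) else None
        curve_rows = sub[sub["speed_pct_ucrit"] >= RMR_SPEED_CUTOFF_PCT]
        points = [
            MetabolicPoint(speed_pct_ucrit=float(r.speed_pct_ucrit), mo2=float(r.mo2_umol_g_h))
            for r in curve_rows.itertuples()
        ]
        results.append(
            analyze_fish(fish_records[fish_id], ucrit_by_fish[fish_id], points, rmr=rmr)
        )
    per_fish = pd.DataFrame([vars(r) for r in results])
    group = summarize_group(results) if len(results) >= 2 else pd.DataFrame()

    # pooled mode: one curve through the speed-wise mean VO2 values
    pooled: dict = {}
    curve_pts = points_df[points_df["speed_pct_ucrit"] >= RMR_SPEED_CUTOFF_PCT]
    mean_vo2 = curve_pts.groupby("speed_pct_ucrit")["mo2_umol_g_h"].mean()
    if mean_vo2.size >= 3:
        speeds = mean_vo2.index.to_numpy(dtype=float)
        values = mean_vo2.to_numpy(dtype=float)
        vo2_curve = fit_vo2_curve(
            [MetabolicPoint(speed_pct_ucrit=s, mo2=v) for s, v in zip(speeds, values)]
        )
        cot_curve = fit_cot_curve(speeds, cot_from_vo2(values, speeds, scale="per_speed_unit"))
        uopt_pct, cot_opt = find_uopt(cot_curve)
        pooled = {
            "smr": vo2_curve.smr,
            "a": vo2_curve.a,
            "b": vo2_curve.b,
            "vo2_r_squared": vo2_curve.r_squared,
            "cot_a2": cot_curve.a2,
            "cot_b2": cot_curve.b2,
            "cot_c2": cot_curve.c2,
            "uopt_pct_ucrit": uopt_pct,
            "cot_opt_curve": cot_opt,
        }
    return per_fish, group, pooled


def run_pipeline(config: zio.RunConfig) -> dict:
    """Execute every stage whose inputs are configured; return the summary.

    Writes per-stage tidy CSVs and ``summary.json`` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    fish_records = {}
    if config.fish_csv is not None:
        fish_records = zio.fish_records_from_cohort(zio.read_cohort_csv(config.fish_csv))

    ucrit_by_fish: dict[str, float] = {}
    if config.trials_csv is not None:
        events = zio.read_trial_csv(config.trials_csv)
        ucrit_by_fish = {
            fid: ucrit_from_events(evs, policy=config.ucrit_policy) for fid, evs in events.items()
        }
        ucrit_df = pd.DataFrame(
            sorted(ucrit_by_fish.items()), columns=["fish_id", "ucrit_ms"]
        )
        ucrit_df.to_csv(out / "ucrit.csv", index=False)
        summary["ucrit_ms_mean"] = float(np.mean(list(ucrit_by_fish.values())))

    points_df = pd.DataFrame()
    if config.traces_csv is not None:
        points_df = _respirometry_stage(config, fish_records)
        points_df.to_csv(out / "mo2_points.csv", index=False)

    if len(points_df) and ucrit_by_fish:
        per_fish, group, pooled = _economy_stage(config, points_df, ucrit_by_fish, fish_records)
        per_fish.to_csv(out / "swim_fitness_per_fish.csv", index=False)
        if len(group):
            group.to_csv(out / "swim_fitness_group.csv")
            summary["economy_group"] = {
                k: {"mean": row["mean"], "sem": row["sem"], "n": int(row["n"])}
                for k, row in group.iterrows()
            }
        if pooled:
            summary["economy_pooled"] = pooled

    if config.cohort_csv is not None:
        cohort = zio.read_cohort_csv(config.cohort_csv)
        battery = run_growth_battery(cohort)
        battery.to_csv(out / "growth_comparisons.csv", index=False)
        summary["growth"] = {
            f"{row.variable}|{row.groups}": {
                "t": row.t_statistic,
                "p": row.p_value,
                "percent_difference": row.percent_difference,
            }
            for row in battery.itertuples()
        }

    if config.ct_csv is not None:
        ct = zio.read_ct_csv(config.ct_csv)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = analyze_expression(
                ct,
                sd_threshold=config.ct_sd_threshold,
                max_outlier_removals=config.max_outlier_removals,
                outlier_alpha=config.outlier_alpha,
            )
        table = expression_table(results)
        table.to_csv(out / "expression_fold_changes.csv", index=False)
        summary["expression"] = {
            row.gene: {"fc": row.fc_mean, "fc_sem": row.fc_sem, "p": row.p_value}
            for row in table.itertuples()
        }

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
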