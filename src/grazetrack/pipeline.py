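"""End-to-end processing: collar file tree -> tidy metrics -> study summaries.

The staged flow mirrors how the collar data are handled in practice:
ingest and clean each logger file, geofence to the paddock boundary, split
into calendar days, compute distance/rate metrics and activity budgets, zone
occupancy and density surfaces, then aggregate animal-days to paddock,
treatment, and period levels for the RCBD analysis.
"""

from __future__ import annotations

import glob
import json
import logging
import os

import numpy as np
import pandas as pd

from grazetrack import site_use, study_summaries
from grazetrack.activity_budget import SpeedThresholds, budgets_table
from grazetrack.geometry import zones_from_geojson
from grazetrack.gps_io import filter_to_boundary, read_gps_log, split_days
from grazetrack.trajectory_metrics import daily_metrics_table

log = logging.getLogger("grazetrack")


def process_tree(
    data_dir,
    out_dir,
    timezone: str = "UTC",
    min_coverage: float = 0.8,
    thresholds: SpeedThresholds = SpeedThresholds(),
    max_gap_s: float = 300.0,
    kde_bandwidth_m: float = 10.0,
    kde_cell_m: float = 1.0,
    kde_kernel: str = "quartic",
    write_density: bool = True,
    expected_rate_hz: float = 1.0,
) -> dict:
    """Process every collar CSV under ``data_dir``; write tidy outputs.

    Expects the layout ``simulate_study`` emits: ``collar_<animal>_<period>.csv``
    plus ``zones_<paddock>.geojson`` containing a ``paddock_boundary`` feature
    and the zones of interest.  Writes daily_metrics.csv, activity_budgets.csv,
    zone_occupancy.csv, per-paddock density grids (.asc), and a JSON run log.
    """
    os.makedirs(out_dir, exist_ok=True)
    collar_files = sorted(glob.glob(os.path.join(data_dir, "collar_*.csv")))
    if not collar_files:
        raise FileNotFoundError(f"no collar files under {data_dir}")

    metrics_rows, budget_rows, occupancy_rows = [], [], []
    paddock_points: dict[str, list] = {}
    counts = {"files": 0, "fixes_in": 0, "fixes_kept": 0, "skipped_files": []}

    for path in collar_files:
        period = os.path.splitext(os.path.basename(path))[0].split("_")[-1]
        try:
            traj, read_rep = read_gps_log(path, dialect="csv")
        except ValueError as exc:
            log.warning("skipping %s: %s", path, exc)
            counts["skipped_files"].append(os.path.basename(path))
            continue
        counts["files"] += 1
        counts["fixes_in"] += read_rep.n_input

        zones_path = os.path.join(data_dir, f"zones_{traj.paddock_id}.geojson")
        zones = zones_from_geojson(zones_path)
        boundary = next(z for z in zones if z.name == "paddock_boundary")
        interest = [z for z in zones if z.name != "paddock_boundary"]

        traj, fence_rep = filter_to_boundary(traj, boundary.geometry)
        counts["fixes_kept"] += fence_rep.n_kept
        segments = split_days(traj, timezone=timezone, min_coverage=min_coverage, expected_rate_hz=expected_rate_hz)

        dm = daily_metrics_table(segments, max_gap_s=max_gap_s)
        dm["period"] = period
        metrics_rows.append(dm)
        bt = budgets_table(segments, thresholds, max_gap_s=max_gap_s)
        bt["period"] = period
        budget_rows.append(bt)

        for seg in segments:
            if seg.excluded or len(seg.trajectory) == 0:
                continue
            occ = site_use.zone_occupancy(seg.trajectory, interest)
            occ["area_m2"] = [z.area_m2 for z in interest]
            occ["paddock_area_m2"] = boundary.area_m2
            occ.insert(0, "animal_id", traj.animal_id)
            occ.insert(1, "paddock_id", traj.paddock_id)
            occ.insert(2, "date", seg.date)
            occ["period"] = period
            occupancy_rows.append(occ)

        if write_density:
            x, y = traj.xy
            paddock_points.setdefault(traj.paddock_id, []).append(np.column_stack([x, y]))

    daily_metrics = pd.concat(metrics_rows, ignore_index=True)
    budgets = pd.concat(budget_rows, ignore_index=True)
    occupancy = pd.concat(occupancy_rows, ignore_index=True) if occupancy_rows else pd.DataFrame()

    daily_metrics.to_csv(os.path.join(out_dir, "daily_metrics.csv"), index=False)
    budgets.to_csv(os.path.join(out_dir, "activity_budgets.csv"), index=False)
    occupancy.to_csv(os.path.join(out_dir, "zone_occupancy.csv"), index=False)

    grids = {}
    if write_density:
        for paddock_id, parts in paddock_points.items():
            pts = np.concatenate(parts)
            grid = site_use.kernel_density(pts, bandwidth_m=kde_bandwidth_m, cell_size_m=kde_cell_m, kernel=kde_kernel)
            grid.to_ascii_grid(os.path.join(out_dir, f"density_{paddock_id}.asc"))
            grids[paddock_id] = grid

    run_log = {
        "n_files": counts["files"],
        "n_fixes_in": counts["fixes_in"],
        "n_fixes_kept": counts["fixes_kept"],
        "skipped_files": counts["skipped_files"],
        "timezone": timezone,
        "min_coverage": min_coverage,
        "thresholds": [thresholds.rest_max_m_per_min, thresholds.travel_min_m_per_min],
        "kde": {"bandwidth_m": kde_bandwidth_m, "cell_m": kde_cell_m, "kernel": kde_kernel},
    }
    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(run_log, fh, indent=2)

    return {"daily_metrics": daily_metrics, "budgets": budgets, "occupancy": occupancy, "grids": grids, "run_log": run_log}


def summarize(metrics_dir, design_csv, out_dir) -> dict:
    """Aggregate processed metrics to treatment x period tables + ANOVA.

    Produces, per metric (distance, rate, resting/grazing/traveling %),
    the treatment x period cell-mean table with SEM and treatment letter
    groups, plus derived statistics: percent distance change of weed-infested
    vs weed-free, cross-treatment activity means, occupancy hours, and strip
    LPIs where strip zones are present.
    """
    os.makedirs(out_dir, exist_ok=True)
    daily_metrics = pd.read_csv(os.path.join(metrics_dir, "daily_metrics.csv"))
    budgets = pd.read_csv(os.path.join(metrics_dir, "activity_budgets.csv"))
    design = pd.read_csv(design_csv)

    merged = daily_metrics.merge(
        budgets[["animal_id", "date", "resting_pct", "grazing_pct", "traveling_pct"]],
        on=["animal_id", "date"],
        how="left",
    )
    merged = merged[~merged["excluded"].astype(bool)]

    value_cols = ["distance_m_per_day", "mean_rate_m_per_min", "resting_pct", "grazing_pct", "traveling_pct"]
    pdaily = study_summaries.paddock_daily_means(merged, value_cols=value_cols)
    pdaily = pdaily.merge(merged[["paddock_id", "date", "period"]].drop_duplicates(), on=["paddock_id", "date"])
    pdaily = study_summaries.attach_design(pdaily, design)

    # paddock x period cells (mean over the period's days)
    cells = pdaily.groupby(["treatment", "block", "period", "paddock_id"], as_index=False)[value_cols].mean()

    results = {"anova": {}, "tables": {}}
    anova_rows = []
    for col in value_cols:
        res = study_summaries.rcbd_anova(cells.rename(columns={col: "value"}), "value")
        results["anova"][col] = res
        tab = study_summaries.treatment_period_table(cells, col)
        tab.to_csv(os.path.join(out_dir, f"table_{col}.csv"), index=False)
        results["tables"][col] = tab
        at = res.table.reset_index(names="effect")
        at.insert(0, "metric", col)
        anova_rows.append(at)
    pd.concat(anova_rows, ignore_index=True).to_csv(os.path.join(out_dir, "anova.csv"), index=False)

    tm = {c: results["anova"][c].treatment_means for c in value_cols}
    derived = {
        "distance_pct_change_infested_vs_free": study_summaries.percent_change(
            tm["distance_m_per_day"].get("weed_infested", np.nan),
            tm["distance_m_per_day"].get("weed_free", np.nan),
        ),
        "cross_treatment_resting_pct": study_summaries.cross_treatment_mean(tm["resting_pct"].to_numpy()),
        "cross_treatment_grazing_pct": study_summaries.cross_treatment_mean(tm["grazing_pct"].to_numpy()),
        "cross_treatment_traveling_pct": study_summaries.cross_treatment_mean(tm["traveling_pct"].to_numpy()),
    }

    occ_path = os.path.join(metrics_dir, "zone_occupancy.csv")
    if os.path.exists(occ_path):
        occ = pd.read_csv(occ_path)
        if len(occ):
            zmeans = occ.groupby("zone")["pct_of_day"].mean()
            for zone, pct in zmeans.items():
                derived[f"occupancy_pct_{zone}"] = float(pct)
                derived[f"occupancy_hours_{zone}"] = study_summaries.frac_to_hours(float(pct))
            if "area_m2" in occ.columns:
                afrac = (occ["area_m2"] / occ["paddock_area_m2"]).groupby(occ["zone"]).mean()
                for zone, pct in zmeans.items():
                    derived[f"lpi_{zone}"] = site_use.lpi(float(pct) / 100.0, float(afrac[zone]), zone=zone).lpi

    with open(os.path.join(out_dir, "derived_stats.json"), "w") as fh:
        json.dump({k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v) for k, v in derived.items()}, fh, indent=2)
    results["derived"] = derived
    return results
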