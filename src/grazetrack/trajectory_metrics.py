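"""Step distances, daily distance traveled, and rate of travel.

Distances are Euclidean (Pythagorean) between sequential planar fixes and
summed over 24 h windows to give m/day.  The rate of travel (m/min) is the
traveled distance divided by the time taken to *change* position, so runs of
identical coordinates are first collapsed (:func:`collapse_stationary`) and
the elapsed stationary time is charged to the step that finally moves.  This
is why mean rates of travel exceed daily distance / 1440.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from grazetrack.gps_io import Trajectory

#: step columns produced by :func:`step_metrics`
STEP_COLUMNS = ["t_start", "t_end", "dt_s", "distance_m", "speed_m_per_min", "valid"]


def collapse_stationary(traj: Trajectory) -> Trajectory:
    """Collapse consecutive fixes with identical coordinates to the first.

    The elapsed time to the next distinct position is preserved implicitly:
    the surviving fix keeps its original timestamp, so the following step's
    ``dt`` covers the whole stationary run.
    """
    x, y = traj.xy
    if len(x) == 0:
        return traj
    keep = np.ones(len(x), dtype=bool)
    keep[1:] = (np.diff(x) != 0) | (np.diff(y) != 0)
    return traj.with_fixes(traj.fixes.loc[keep])


def step_metrics(traj: Trajectory, max_gap_s: float = 300.0, collapse: bool = True) -> pd.DataFrame:
    """Per-step distance (m) and speed (m/min) for a planar trajectory.

    By default speeds are computed on the stationary-collapsed series
    (distance over time-to-change-position); pass ``collapse=False`` for raw
    per-fix steps.  A step is marked invalid when it spans a *recording* gap
    (raw inter-fix interval above ``max_gap_s``); a long time-to-change-
    position over continuously recorded identical fixes is stationary time,
    not a gap, and stays valid.
    """

    def _epoch_s(series):
        return series.astype("int64").to_numpy() / 1e9

    t_raw = _epoch_s(traj.fixes["time"])
    if len(t_raw) >= 2 and np.any(np.diff(t_raw) <= 0):
        raise ValueError("non-monotone timestamps in trajectory")

    if collapse:
        x_all, y_all = traj.xy
        keep = np.ones(len(x_all), dtype=bool)
        if len(x_all) > 1:
            keep[1:] = (np.diff(x_all) != 0) | (np.diff(y_all) != 0)
        kept_idx = np.nonzero(keep)[0]
        work = traj.with_fixes(traj.fixes.loc[keep])
    else:
        kept_idx = np.arange(len(traj))
        work = traj

    x, y = work.xy
    t = _epoch_s(work.fixes["time"])
    if len(x) < 2:
        return pd.DataFrame(columns=STEP_COLUMNS)
    dt = np.diff(t)
    dist = np.hypot(np.diff(x), np.diff(y))
    speed = dist / (dt / 60.0)

    # a collapsed step i spans raw fixes kept_idx[i] .. kept_idx[i+1]
    raw_gap = np.diff(t_raw) > max_gap_s
    gap_cum = np.concatenate([[0], np.cumsum(raw_gap)])
    valid = (gap_cum[kept_idx[1:]] - gap_cum[kept_idx[:-1]]) == 0

    return pd.DataFrame(
        {
            "t_start": work.fixes["time"].iloc[:-1].to_numpy(),
            "t_end": work.fixes["time"].iloc[1:].to_numpy(),
            "dt_s": dt,
            "distance_m": dist,
            "speed_m_per_min": speed,
            "valid": valid,
        }
    )


def daily_distance(steps: pd.DataFrame) -> float:
    """Total distance (m) over one day's valid steps."""
    if len(steps) == 0:
        return 0.0
    return float(steps.loc[steps["valid"], "distance_m"].sum())


def mean_rate_of_travel(steps: pd.DataFrame) -> float:
    """Time-weighted mean rate of travel (m/min) over valid steps:
    total distance over total time-to-change-position."""
    v = steps.loc[steps["valid"]]
    if len(v) == 0 or v["dt_s"].sum() == 0:
        return 0.0
    return float(v["distance_m"].sum() / (v["dt_s"].sum() / 60.0))


def resample(traj: Trajectory, interval_s: float) -> Trajectory:
    """Thin a trajectory to the fix nearest each ``interval_s`` tick.

    Used to quantify the interpolation error of coarser sampling schedules:
    on sinuous paths the resampled daily distance underestimates the native
    one (chords are shorter than arcs).
    """
    t = traj.fixes["time"].astype("int64").to_numpy() / 1e9
    if len(t) < 2:
        return traj
    native = np.median(np.diff(t))
    if interval_s < native:
        raise ValueError(f"interval {interval_s}s below native spacing {native}s")
    ticks = np.arange(t[0], t[-1] + interval_s / 2, interval_s)
    idx = np.searchsorted(t, ticks)
    idx = np.clip(idx, 0, len(t) - 1)
    # choose nearer of the two bracketing fixes
    idx_prev = np.clip(idx - 1, 0, len(t) - 1)
    nearer_prev = np.abs(t[idx_prev] - ticks) < np.abs(t[idx] - ticks)
    idx = np.where(nearer_prev, idx_prev, idx)
    idx = np.unique(idx)
    return traj.with_fixes(traj.fixes.iloc[idx])


def daily_metrics_table(day_segments, max_gap_s: float = 300.0) -> pd.DataFrame:
    """Tidy one-row-per-animal-day table of distance and travel-rate metrics."""
    rows = []
    for seg in day_segments:
        traj = seg.trajectory
        steps = step_metrics(traj, max_gap_s=max_gap_s)
        rows.append(
            {
                "animal_id": traj.animal_id,
                "paddock_id": traj.paddock_id,
                "date": seg.date,
                "n_fixes": len(traj),
                "coverage": seg.coverage,
                "excluded": seg.excluded,
                "distance_m_per_day": daily_distance(steps),
                "mean_rate_m_per_min": mean_rate_of_travel(steps),
            }
        )
    return pd.DataFrame(rows)
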