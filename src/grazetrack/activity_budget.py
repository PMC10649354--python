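"""Speed-threshold activity classification and daily activity budgets.

Movement rate is mapped to three behavioral states used for grazing steers:
below 2.34 m/min is resting (all stationary behavior, including rumination),
between 2.34 and 25 m/min inclusive is grazing, and above 25 m/min is
traveling.  Budgets are dt-weighted percentages of classified time per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STATES = ("resting", "grazing", "traveling")


@dataclass(frozen=True)
class SpeedThresholds:
    """Classification bands in m/min.  Boundary values fall to grazing."""

    rest_max_m_per_min: float = 2.34
    travel_min_m_per_min: float = 25.0

    def __post_init__(self):
        if not (0 < self.rest_max_m_per_min < self.travel_min_m_per_min):
            raise ValueError("thresholds must satisfy 0 < rest_max < travel_min")


@dataclass(frozen=True)
class ActivityBudget:
    """Daily percentages of classified time per state (sum to 100)."""

    animal_id: str
    date: object
    resting_pct: float
    grazing_pct: float
    traveling_pct: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.resting_pct, self.grazing_pct, self.traveling_pct)


def classify_speed(v_m_per_min, thresholds: SpeedThresholds = SpeedThresholds()):
    """Classify speeds (m/min) into resting / grazing / traveling.

    Scalar in, scalar out; array in, object array of state labels out.
    """
    v = np.asarray(v_m_per_min, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative speed")
    out = np.where(
        v < thresholds.rest_max_m_per_min,
        "resting",
        np.where(v > thresholds.travel_min_m_per_min, "traveling", "grazing"),
    )
    if out.ndim == 0:
        return str(out)
    return out


def daily_budget(
    steps: pd.DataFrame,
    thresholds: SpeedThresholds = SpeedThresholds(),
    animal_id: str = "",
    date=None,
) -> ActivityBudget:
    """dt-weighted activity budget for one day's step series.

    Stationary-collapsed runs carry their elapsed time in the following
    step's ``dt``; their speed reflects the time to change position, so long
    immobile runs land in the resting band.  Percentages are of classified
    (valid-step) time, not wall-clock time, so dropout days stay unbiased.
    """
    v = steps.loc[steps["valid"]] if "valid" in steps else steps
    total = v["dt_s"].sum()
    if len(v) == 0 or total <= 0:
        raise ValueError("no classified time in day")
    labels = classify_speed(v["speed_m_per_min"].to_numpy(), thresholds)
    pct = {}
    for s in STATES:
        pct[s] = 100.0 * float(v["dt_s"].to_numpy()[labels == s].sum()) / total
    return ActivityBudget(
        animal_id=animal_id,
        date=date,
        resting_pct=pct["resting"],
        grazing_pct=pct["grazing"],
        traveling_pct=pct["traveling"],
    )


def day_budget_from_trajectory(
    traj,
    thresholds: SpeedThresholds = SpeedThresholds(),
    max_gap_s: float = 300.0,
    date=None,
) -> ActivityBudget:
    """Budget for one daily trajectory; a fully stationary day (no position
    change at all, hence no steps) is 100% resting by definition."""
    from grazetrack.trajectory_metrics import step_metrics

    steps = step_metrics(traj, max_gap_s=max_gap_s)
    if len(steps) == 0:
        if len(traj) == 0:
            raise ValueError("empty trajectory")
        return ActivityBudget(traj.animal_id, date, 100.0, 0.0, 0.0)
    return daily_budget(steps, thresholds, animal_id=traj.animal_id, date=date)


def budgets_table(day_segments, thresholds: SpeedThresholds = SpeedThresholds(), max_gap_s: float = 300.0) -> pd.DataFrame:
    """Tidy per-animal-day budget table from daily trajectory segments."""
    rows = []
    for seg in day_segments:
        traj = seg.trajectory
        if len(traj) == 0:
            continue
        b = day_budget_from_trajectory(traj, thresholds, max_gap_s=max_gap_s, date=seg.date)
        rows.append(
            {
                "animal_id": traj.animal_id,
                "paddock_id": traj.paddock_id,
                "date": seg.date,
                "excluded": seg.excluded,
                "resting_pct": b.resting_pct,
                "grazing_pct": b.grazing_pct,
                "traveling_pct": b.traveling_pct,
            }
        )
    return pd.DataFrame(rows)
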