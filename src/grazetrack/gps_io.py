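"""Reading, cleaning, geofencing, and daily segmentation of GPS logger data.

Collar loggers record one fix per second (timestamp, latitude, longitude)
for ~21-day deployments.  Raw logs contain duplicate timestamps, out-of-order
rows, and fixes recorded outside the paddock (e.g. on the pen-to-paddock
walk); everything outside the paddock boundary is excluded before analysis,
and every removal is counted in a :class:`FilterReport`.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, asdict, replace
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from grazetrack.geometry import points_in_polygon, polygon_area

#: default CSV column mapping for collar exports and the synthetic emitter
DEFAULT_COLUMN_MAP = {"time": "time", "lat": "lat", "lon": "lon", "x": "x", "y": "y"}


@dataclass(frozen=True)
class GpsFix:
    """One GPS position record."""

    time: pd.Timestamp
    lat: float | None = None
    lon: float | None = None
    x: float | None = None
    y: float | None = None
    animal_id: str = ""
    paddock_id: str = ""


@dataclass
class FilterReport:
    """Audit counts for a cleaning/filtering step.

    Invariant: ``n_input == n_kept + n_out_of_boundary + n_duplicate``.
    """

    n_input: int = 0
    n_kept: int = 0
    n_out_of_boundary: int = 0
    n_duplicate: int = 0
    n_reordered: int = 0
    n_unparseable: int = 0  # rows skipped before the fix-level accounting

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class Trajectory:
    """Ordered fixes for one animal, geographic or planar.

    ``fixes`` is a DataFrame with a UTC ``time`` column plus ``lat``/``lon``
    (geographic) or ``x``/``y`` meters (planar); sorted by time with no
    duplicate timestamps.
    """

    fixes: pd.DataFrame
    crs_state: str = "geographic"  # "geographic" | "planar"
    animal_id: str = ""
    paddock_id: str = ""
    period: str | None = None

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        if self.crs_state != "planar":
            raise ValueError("trajectory is not planar; project it first")
        return self.fixes["x"].to_numpy(), self.fixes["y"].to_numpy()

    def with_fixes(self, df: pd.DataFrame) -> "Trajectory":
        return replace(self, fixes=df.reset_index(drop=True))

    def to_csv(self, path) -> None:
        df = self.fixes.copy()
        df.insert(0, "animal_id", self.animal_id)
        df.insert(1, "paddock_id", self.paddock_id)
        df.to_csv(path, index=False)


def _finalize(df: pd.DataFrame, report: FilterReport) -> tuple[pd.DataFrame, FilterReport]:
    """Sort by time and collapse duplicate timestamps (keep first)."""
    order = df["time"].astype("int64").to_numpy()
    # fixes with a timestamp earlier than one already seen in file order
    n_reordered = int(np.sum(order[1:] < np.maximum.accumulate(order)[:-1])) if len(order) > 1 else 0
    if n_reordered:
        df = df.sort_values("time", kind="stable")
    dup = df["time"].duplicated(keep="first")
    report.n_duplicate = int(dup.sum())
    report.n_reordered = n_reordered
    df = df.loc[~dup].reset_index(drop=True)
    report.n_kept = len(df)
    return df, report


def read_gps_log(
    path,
    dialect: str = "csv",
    column_map: dict | None = None,
    time_format: str | None = None,
    animal_id: str = "",
    paddock_id: str = "",
) -> tuple[Trajectory, FilterReport]:
    """Parse a collar log into a clean :class:`Trajectory`.

    Fixes are sorted by timestamp and exact-duplicate timestamps collapsed to
    their first occurrence; unparseable rows are skipped and counted.  CSV
    column names are configurable via ``column_map`` (keys ``time``, ``lat``,
    ``lon`` or ``x``, ``y``); GPX 1.1 track points are also supported.
    """
    if dialect not in ("csv", "gpx"):
        raise ValueError(f"unknown dialect {dialect!r}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    if dialect == "gpx":
        df = _read_gpx(path)
        crs_state = "geographic"
    else:
        raw = pd.read_csv(path)
        if raw.empty:
            raise ValueError(f"empty GPS log: {path}")
        df = pd.DataFrame()
        df["time"] = pd.to_datetime(raw[cmap["time"]], format=time_format, utc=True, errors="coerce")
        planar = cmap["x"] in raw.columns and cmap["y"] in raw.columns
        if planar:
            df["x"] = pd.to_numeric(raw[cmap["x"]], errors="coerce")
            df["y"] = pd.to_numeric(raw[cmap["y"]], errors="coerce")
            crs_state = "planar"
        elif cmap["lat"] in raw.columns and cmap["lon"] in raw.columns:
            df["lat"] = pd.to_numeric(raw[cmap["lat"]], errors="coerce")
            df["lon"] = pd.to_numeric(raw[cmap["lon"]], errors="coerce")
            crs_state = "geographic"
        else:
            raise ValueError("CSV lacks mappable position columns (lat/lon or x/y)")
        if not animal_id and "animal_id" in raw.columns:
            animal_id = str(raw["animal_id"].iloc[0])
        if not paddock_id and "paddock_id" in raw.columns:
            paddock_id = str(raw["paddock_id"].iloc[0])

    bad = df.isna().any(axis=1)
    df = df.loc[~bad]
    if df.empty:
        raise ValueError(f"no parseable fixes in {path}")
    # n_input counts parseable fixes; skipped rows are reported separately
    report = FilterReport(n_input=len(df), n_unparseable=int(bad.sum()))
    df, report = _finalize(df, report)

    if crs_state == "geographic":
        ok = (df["lat"].between(-90, 90) & df["lon"].between(-180, 180)).to_numpy()
        if not ok.all():
            raise ValueError("coordinates outside WGS84 bounds")

    traj = Trajectory(fixes=df.reset_index(drop=True), crs_state=crs_state, animal_id=animal_id, paddock_id=paddock_id)
    return traj, report


def _read_gpx(path) -> pd.DataFrame:
    tree = ET.parse(path)
    root = tree.getroot()
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    rows = []
    for trkpt in root.iter(f"{ns}trkpt"):
        t = trkpt.find(f"{ns}time")
        if t is None or t.text is None:
            continue
        try:
            rows.append(
                {
                    "time": pd.Timestamp(t.text).tz_localize("UTC") if pd.Timestamp(t.text).tzinfo is None else pd.Timestamp(t.text),
                    "lat": float(trkpt.attrib["lat"]),
                    "lon": float(trkpt.attrib["lon"]),
                }
            )
        except (KeyError, ValueError):
            continue
    if not rows:
        raise ValueError(f"no track points in GPX file {path}")
    df = pd.DataFrame(rows)
    df["time"] = pd.to_datetime(df["time"], utc=True)
    return df


def filter_to_boundary(traj: Trajectory, boundary: Polygon) -> tuple[Trajectory, FilterReport]:
    """Geofence: keep only fixes inside or on the paddock boundary.

    Removes collar fixes recorded outside the paddock (pen, laneway, GPS
    excursions).  Order is preserved; the closed convention keeps fence-line
    fixes.  Idempotent.
    """
    polygon_area(boundary)  # raises on degenerate boundary
    x, y = traj.xy
    inside = points_in_polygon(x, y, boundary)
    report = FilterReport(
        n_input=len(traj),
        n_kept=int(inside.sum()),
        n_out_of_boundary=int((~inside).sum()),
    )
    return traj.with_fixes(traj.fixes.loc[inside]), report


@dataclass
class DaySegment:
    """One local calendar day of fixes for one animal."""

    trajectory: Trajectory
    date: object  # datetime.date in the study timezone
    coverage: float
    excluded: bool


def split_days(
    traj: Trajectory,
    timezone: str = "UTC",
    min_coverage: float = 0.8,
    expected_rate_hz: float = 1.0,
) -> list[DaySegment]:
    """Split a trajectory into local-calendar-day segments.

    Days whose fix count falls below ``min_coverage`` of the expected
    ``86400 * expected_rate_hz`` fixes are flagged ``excluded`` (this is how
    collar-recharge days drop out).  Fixes straddling midnight are assigned
    to exactly one day.
    """
    tz = ZoneInfo(timezone)
    local = traj.fixes["time"].dt.tz_convert(tz)
    dates = local.dt.date
    expected = 86400.0 * expected_rate_hz
    segments = []
    for date, idx in traj.fixes.groupby(dates.to_numpy(), sort=True).groups.items():
        df = traj.fixes.loc[idx]
        coverage = len(df) / expected
        segments.append(
            DaySegment(
                trajectory=traj.with_fixes(df),
                date=date,
                coverage=coverage,
                excluded=coverage < min_coverage,
            )
        )
    return segments
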