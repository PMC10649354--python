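"""Synthetic GPS-collar herd datasets with known ground truth.

The study data (1 Hz collar fixes, 2 tester steers per ~1.3 ha paddock,
21-day periods, <10 m location error) is not publicly deposited, so this
module generates collar-like datasets whose behavioral ground truth is known
exactly, making every pipeline stage testable.

Movement model: behavior alternates among rest / graze / travel bouts
(semi-Markov, exponential bout durations).  When a target daily activity
budget is specified the scheduler switches to quota mode: each state's total
time per day is fixed at its budget share, split into exponential-length
bouts and randomly interleaved, so the realized ground-truth budget equals
the design target and downstream classification error measures the
classifier, not bout-sampling noise.  Within moving bouts the animal follows
a correlated random walk (wrapped-Cauchy turning angles) at per-step
log-normal speeds; with a "separable" configuration the speeds stay strictly
inside the classifier bands.  The paddock fence is reflective.  On bout
switches the animal may relocate toward an attractor zone (shade, water)
with configured probability, which produces the hotspot / preference
structure seen in real herds.

GPS error model: the logger's horizontal error is a slowly wandering bias,
not per-second white noise — at 1 Hz a stationary animal produces long runs
of identical coordinates, and these devices' speed classification works in
practice precisely because of that.  We emulate it with an
Ornstein–Uhlenbeck error process (marginal SD ``gps_noise_sd_m``,
correlation time ``noise_corr_time_s``) sampled with a zero-order hold every
``noise_update_s`` seconds (the receiver's effective solution-update rate),
plus coordinate quantization at the logger's output resolution
(``quantize_m``).  This reproduces both phenomena described for such
devices: daily-distance overestimation growing with the error SD, and long
identical-coordinate runs while resting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from grazetrack.activity_budget import STATES, SpeedThresholds
from grazetrack.geometry import Zone
from grazetrack.gps_io import Trajectory


# ------------------------------------------------------------- configuration

@dataclass(frozen=True)
class StateParams:
    """Movement parameters for one behavioral state."""

    mean_bout_s: float
    speed_m_per_min: float  # mean speed while in the state (0 = stationary)
    speed_sigma: float = 0.15  # log-normal shape of per-step speed jitter


def default_states() -> dict:
    return {
        "resting": StateParams(mean_bout_s=1200.0, speed_m_per_min=0.0),
        "grazing": StateParams(mean_bout_s=300.0, speed_m_per_min=8.0),
        "traveling": StateParams(mean_bout_s=90.0, speed_m_per_min=55.0),
    }


def default_zones(width_m: float = 130.0, height_m: float = 100.0) -> list[Zone]:
    """Shade and water structures near the paddock edge, 10 m buffered."""
    shade = Zone("shade", box(width_m * 0.15, height_m * 0.75, width_m * 0.15 + 6, height_m * 0.75 + 6)).buffer(10.0)
    water = Zone("water", box(width_m * 0.85 - 2, height_m * 0.1, width_m * 0.85, height_m * 0.1 + 2)).buffer(10.0)
    return [shade, water]


def strip_zones(width_m: float = 130.0, height_m: float = 100.0, weed_share: float = 0.48) -> list[Zone]:
    """Exhaustive two-strip partition: weed strip share vs grass strip."""
    xsplit = width_m * weed_share
    return [
        Zone("weed_strip", box(0, 0, xsplit, height_m)),
        Zone("bermudagrass_strip", box(xsplit, 0, width_m, height_m)),
    ]


@dataclass
class SimulationConfig:
    """Conditions for one simulated collar deployment.

    Defaults mirror the study setup: a 130 x 100 m (~1.3 ha) paddock, 1 Hz
    fixes over full days, a cross-treatment activity budget of
    87.2 / 7.6 / 5.2 % (rest / graze / travel), and a 5 m GPS error SD
    (device error < 10 m).
    """

    width_m: float = 130.0
    height_m: float = 100.0
    zones: list = field(default_factory=default_zones)
    n_days: int = 1
    day_seconds: int = 86400
    fix_rate_hz: float = 1.0
    states: dict = field(default_factory=default_states)
    target_budget: tuple | None = (87.2, 7.6, 5.2)  # rest, graze, travel %
    # probability that a rest is preceded by a goal-directed walk to the zone;
    # defaults sized so roughly a fifth of the day is loafed in shade and a
    # tenth at water, the pattern seen in confined grazing cattle
    attraction: dict = field(default_factory=lambda: {"shade": 0.35, "water": 0.18})
    crw_rho: float = 0.7  # wrapped-Cauchy turning concentration
    heading_jitter_goal: float = 0.15  # rad, while moving toward a goal
    gps_noise_sd_m: float = 5.0
    noise_corr_time_s: float = 3600.0
    noise_update_s: float = 60.0
    quantize_m: float = 0.1
    dropout_prob: float = 0.0
    separable: bool = True
    thresholds: SpeedThresholds = field(default_factory=SpeedThresholds)
    start_time: str = "2022-07-12T00:00:00Z"
    animal_id: str = "A1"
    paddock_id: str = "P1"

    def __post_init__(self):
        if self.target_budget is not None:
            tot = sum(self.target_budget)
            if not math.isclose(tot, 100.0, abs_tol=1.5):
                raise ValueError("target budget must sum to ~100%")
            self.target_budget = tuple(100.0 * b / tot for b in self.target_budget)
        if self.separable:
            th = self.thresholds
            g = self.states["grazing"].speed_m_per_min
            t = self.states["traveling"].speed_m_per_min
            if not (th.rest_max_m_per_min < g < th.travel_min_m_per_min):
                raise ValueError("grazing speed outside the grazing band")
            if not (t > th.travel_min_m_per_min):
                raise ValueError("traveling speed below the traveling band")

    @property
    def boundary(self) -> Polygon:
        return box(0, 0, self.width_m, self.height_m)


def calibrate_travel_speed(budget, daily_distance_m: float, grazing_speed: float = 8.0) -> float:
    """Mean traveling speed (m/min) that yields a target daily distance for a
    given budget, holding grazing speed fixed (resting contributes nothing)."""
    rest, graze, travel = (b / 100.0 for b in budget)
    graze_min = graze * 1440.0
    travel_min_t = travel * 1440.0
    if travel_min_t <= 0:
        raise ValueError("budget has no traveling time")
    v = (daily_distance_m - graze_min * grazing_speed) / travel_min_t
    if v <= 0:
        raise ValueError("target distance unreachable with this budget")
    return v


# ------------------------------------------------------------- ground truth

@dataclass
class GroundTruth:
    """True (noise-free) positions and state labels, one row per fix."""

    data: pd.DataFrame  # time, x_true, y_true, state

    def daily_budget(self) -> pd.DataFrame:
        """True percent of time per state per UTC day."""
        d = self.data
        dates = d["time"].dt.date
        out = (
            d.groupby([dates.to_numpy(), "state"], sort=True)
            .size()
            .unstack("state", fill_value=0)
        )
        out = 100.0 * out.div(out.sum(axis=1), axis=0)
        for s in STATES:
            if s not in out.columns:
                out[s] = 0.0
        out.index.name = "date"
        return out[list(STATES)].reset_index()

    def daily_distance(self) -> pd.Series:
        """True distance (m) per UTC day, summed within-day step lengths."""
        d = self.data
        dx = d["x_true"].diff().to_numpy()
        dy = d["y_true"].diff().to_numpy()
        step = np.hypot(dx, dy)
        step[0] = 0.0
        dates = d["time"].dt.date.to_numpy()
        same_day = np.concatenate([[False], dates[1:] == dates[:-1]])
        ser = pd.Series(np.where(same_day, step, 0.0)).groupby(dates).sum()
        ser.index.name = "date"
        return ser


# -------------------------------------------------------------- primitives

def _fold(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Specular reflection of coordinates into [lo, hi] (triangle-wave map)."""
    span = hi - lo
    z = np.mod(z - lo, 2.0 * span)
    return lo + np.where(z > span, 2.0 * span - z, z)


def _wrapped_cauchy(rng, rho: float, n: int) -> np.ndarray:
    u = rng.random(n)
    return 2.0 * np.arctan(((1.0 - rho) / (1.0 + rho)) * np.tan(np.pi * (u - 0.5)))


def _truncated_lognormal_speeds(rng, mean: float, sigma: float, n: int, lo: float, hi: float) -> np.ndarray:
    """Per-step speeds (m/min) with the given mean, clipped into (lo, hi)."""
    mu = math.log(mean) - sigma**2 / 2.0
    v = rng.lognormal(mu, sigma, n)
    return np.clip(v, lo * 1.02, hi * 0.98)


def _random_point_in(rng, geom) -> tuple[float, float]:
    minx, miny, maxx, maxy = geom.bounds
    for _ in range(200):
        px = rng.uniform(minx, maxx)
        py = rng.uniform(miny, maxy)
        if geom.covers(shapely_point(px, py)):
            return px, py
    c = geom.centroid
    return c.x, c.y


def shapely_point(x, y):
    from shapely.geometry import Point

    return Point(x, y)


def _day_bout_schedule(rng, cfg: SimulationConfig) -> list[tuple[str, int]]:
    """(state, n_steps) bouts covering one day."""
    n_total = int(round(cfg.day_seconds * cfg.fix_rate_hz))
    if cfg.target_budget is not None:
        bouts = []
        for s, pct in zip(STATES, cfg.target_budget):
            quota = pct / 100.0 * n_total
            if quota < 1:
                continue
            mean_steps = cfg.states[s].mean_bout_s * cfg.fix_rate_hz
            k = max(1, int(round(quota / mean_steps)))
            durs = rng.exponential(mean_steps, k)
            durs *= quota / durs.sum()
            bouts.extend((s, d) for d in durs)
        rng.shuffle(bouts)
    else:
        # plain semi-Markov: uniform switch among the other states
        bouts = []
        total = 0.0
        state = "resting"
        while total < n_total:
            d = rng.exponential(cfg.states[state].mean_bout_s * cfg.fix_rate_hz)
            bouts.append((state, d))
            total += d
            others = [s for s in STATES if s != state]
            state = others[rng.integers(len(others))]
    # integer step counts that sum exactly to n_total
    durs = np.array([d for _, d in bouts])
    durs *= n_total / durs.sum()
    edges = np.round(np.concatenate([[0.0], np.cumsum(durs)])).astype(int)
    edges[-1] = n_total
    steps = np.diff(edges)
    return [(s, int(n)) for (s, _), n in zip(bouts, steps) if n > 0]


# --------------------------------------------------------------- simulation

def simulate_trajectory(config: SimulationConfig, seed=0) -> tuple[Trajectory, GroundTruth]:
    """Simulate one collar deployment; reproducible under a fixed seed.

    Returns the observed trajectory (true path + GPS error model, minus
    dropout) and the per-fix ground truth.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    dt = 1.0 / cfg.fix_rate_hz
    W, H = cfg.width_m, cfg.height_m
    th = cfg.thresholds

    zone_names = [z.name for z in cfg.zones]
    attract_zones = [z for z in cfg.zones if cfg.attraction.get(z.name, 0.0) > 0]
    attract_p = np.array([cfg.attraction[z.name] for z in attract_zones])

    xs_all, ys_all, states_all = [], [], []
    x, y = W / 2.0, H / 2.0
    heading = rng.uniform(-np.pi, np.pi)
    pending = None  # (goal point, zone) of an in-progress goal-directed walk
    must_leave = False  # walk back into the open paddock after a zone rest

    for _day in range(cfg.n_days):
        schedule = _day_bout_schedule(rng, cfg)
        for bi, (state, n) in enumerate(schedule):
            sp = cfg.states[state]
            if sp.speed_m_per_min <= 0 or n == 0:
                xs_all.append(np.full(n, x))
                ys_all.append(np.full(n, y))
                states_all.append(np.full(n, state, dtype=object))
                continue
            if state == "grazing":
                lo, hi = th.rest_max_m_per_min, th.travel_min_m_per_min
            else:
                lo, hi = th.travel_min_m_per_min, th.travel_min_m_per_min * 8.0
            if not cfg.separable:
                lo, hi = 0.0, np.inf
            v = _truncated_lognormal_speeds(rng, sp.speed_m_per_min, sp.speed_sigma, n, max(lo, 1e-6), min(hi, 1e6))
            step = v / 60.0 * dt  # m per fix interval

            # animals seek shade/water to loaf at: when the upcoming bout is a
            # rest, a goal-directed walk to a zone may start; the goal
            # persists across moving bouts until reached, and the animal then
            # stays tethered in the zone so the rest is taken there
            next_rests = bi + 1 < len(schedule) and cfg.states[schedule[bi + 1][0]].speed_m_per_min <= 0
            if must_leave and pending is None:
                pending = ((rng.uniform(0.15 * W, 0.85 * W), rng.uniform(0.15 * H, 0.85 * H)), None)
                must_leave = False
            if pending is None and attract_p.size and next_rests and rng.random() < attract_p.sum():
                zi = rng.choice(len(attract_zones), p=attract_p / attract_p.sum())
                zone = attract_zones[zi]
                pending = (_random_point_in(rng, zone.geometry), zone)

            if pending is not None:
                (gx, gy), goal_zone = pending
                d0 = math.hypot(gx - x, gy - y)
                cum = np.cumsum(step)
                n1 = int(np.searchsorted(cum, d0))
                n1 = min(n1, n)
                reached = n1 < n or (n > 0 and cum[-1] >= d0)
            else:
                goal_zone = None
                n1 = 0
                reached = False

            dx = np.empty(n)
            dy = np.empty(n)
            if n1 > 0:
                base = math.atan2(gy - y, gx - x)
                hd1 = base + rng.normal(0.0, cfg.heading_jitter_goal, n1)
                dx[:n1] = step[:n1] * np.cos(hd1)
                dy[:n1] = step[:n1] * np.sin(hd1)
                heading = base
            if n1 < n:
                turns = _wrapped_cauchy(rng, cfg.crw_rho, n - n1)
                hd2 = heading + np.cumsum(turns)
                dx[n1:] = step[n1:] * np.cos(hd2)
                dy[n1:] = step[n1:] * np.sin(hd2)
                heading = float(np.mod(hd2[-1] + np.pi, 2 * np.pi) - np.pi)

            px = _fold(x + np.cumsum(dx), 0.0, W)
            py = _fold(y + np.cumsum(dy), 0.0, H)
            if reached:
                pending = None
                if goal_zone is not None:
                    # arrived: keep milling about inside the zone until the
                    # bout ends so the upcoming rest happens there, then head
                    # back into the open paddock
                    zx0, zy0, zx1, zy1 = goal_zone.geometry.bounds
                    bx = px[n1 - 1] if n1 > 0 else x
                    by = py[n1 - 1] if n1 > 0 else y
                    if n1 < n:
                        px[n1:] = _fold(bx + np.cumsum(dx[n1:]), max(zx0, 0.0), min(zx1, W))
                        py[n1:] = _fold(by + np.cumsum(dy[n1:]), max(zy0, 0.0), min(zy1, H))
                    must_leave = True
            xs_all.append(px)
            ys_all.append(py)
            states_all.append(np.full(n, state, dtype=object))
            x, y = float(px[-1]), float(py[-1])

    x_true = np.concatenate(xs_all)
    y_true = np.concatenate(ys_all)
    states = np.concatenate(states_all)
    n_total = len(x_true)
    times = pd.Timestamp(cfg.start_time) + pd.to_timedelta(np.arange(n_total) * dt, unit="s")

    truth = GroundTruth(pd.DataFrame({"time": times, "x_true": x_true, "y_true": y_true, "state": states}))

    x_obs, y_obs = apply_gps_error(
        x_true, y_true, cfg.gps_noise_sd_m, cfg.noise_corr_time_s, cfg.quantize_m, cfg.fix_rate_hz, rng,
        update_s=cfg.noise_update_s,
    )

    keep = np.ones(n_total, dtype=bool)
    if cfg.dropout_prob > 0:
        keep = rng.random(n_total) >= cfg.dropout_prob

    fixes = pd.DataFrame({"time": times[keep], "x": x_obs[keep], "y": y_obs[keep]})
    traj = Trajectory(fixes=fixes, crs_state="planar", animal_id=cfg.animal_id, paddock_id=cfg.paddock_id)
    return traj, truth


def apply_gps_error(x, y, sd_m: float, corr_time_s: float, quantize_m: float, fix_rate_hz: float, rng,
                    update_s: float = 60.0) -> tuple[np.ndarray, np.ndarray]:
    """Add the collar GPS error model to a true path.

    Ornstein–Uhlenbeck horizontal error (marginal SD ``sd_m``, correlation
    time ``corr_time_s``) held constant between receiver solution updates
    every ``update_s`` seconds, plus coordinate quantization at
    ``quantize_m``.  ``sd_m = 0`` returns the true positions untouched (no
    quantization), so noiseless runs recover ground truth exactly.
    """
    if sd_m <= 0:
        return np.asarray(x, float).copy(), np.asarray(y, float).copy()
    from scipy.signal import lfilter

    n = len(x)
    k = max(1, int(round(update_s * fix_rate_hz)))  # fixes per error update
    m = int(np.ceil(n / k))
    rho = math.exp(-update_s / corr_time_s)
    out = []
    for arr in (x, y):
        w = rng.normal(0.0, sd_m * math.sqrt(1.0 - rho**2), m)
        w[0] = rng.normal(0.0, sd_m)  # stationary start
        noise = lfilter([1.0], [1.0, -rho], w)
        held = np.repeat(noise, k)[:n]  # zero-order hold between updates
        obs = np.asarray(arr, float) + held
        if quantize_m > 0:
            obs = np.round(obs / quantize_m) * quantize_m
        out.append(obs)
    return out[0], out[1]


# ------------------------------------------------------------ full study sim

TREATMENT_DEFAULTS = {
    # per-treatment target budgets (rest/graze/travel %) and daily distance
    "weed_free": {"budget": (88.8, 6.6, 4.7), "distance_m": 4482.0},
    "weed_strip": {"budget": (87.8, 7.2, 4.9), "distance_m": 5079.0},
    "weed_infested": {"budget": (85.1, 8.9, 6.0), "distance_m": 5657.0},
}


@dataclass
class StudyConfig:
    """The full grazing-study design: 3 treatments x 4 blocks x 2 testers,
    repeated 21-day collar periods."""

    treatments: dict = field(default_factory=lambda: {k: dict(v) for k, v in TREATMENT_DEFAULTS.items()})
    n_blocks: int = 4
    testers_per_paddock: int = 2
    n_periods: int = 5
    days_per_period: int = 21
    period_gap_days: int = 1  # collar recharge day between periods
    base: SimulationConfig = field(default_factory=SimulationConfig)
    budget_day_sd: float = 1.5  # day-to-day jitter on resting %, re-normalized
    distance_day_sigma: float = 0.08  # log-normal day jitter on travel speed
    block_distance_sigma: float = 0.03  # log-normal block effect on speeds
    seed: int = 0


def _jittered_budget(rng, budget, sd):
    b = np.array(budget, float)
    if sd > 0:
        shift = rng.normal(0.0, sd)
        b[0] += shift
        b[1] -= shift * 0.6
        b[2] -= shift * 0.4
        b = np.clip(b, 0.5, None)
    return tuple(100.0 * b / b.sum())


def simulate_study(study: StudyConfig, out_dir=None):
    """Simulate the whole study; optionally emit the file tree.

    Returns a dict with per-animal trajectories, ground truths, the design
    table, and zone layouts.  With ``out_dir`` set, writes collar CSVs (the
    dialect ``read_gps_log`` ingests), ``zones_<paddock>.geojson``,
    ``design.csv`` / ``design.yaml``, and a ground-truth summary CSV.
    """
    rng = np.random.default_rng(study.seed)
    design_rows = []
    bundle = {"trajectories": [], "truths": [], "design": None, "zones": {}}

    treatments = list(study.treatments)
    pad_num = 0
    for block in range(1, study.n_blocks + 1):
        order = rng.permutation(len(treatments))  # randomize within block
        for ti in order:
            trt = treatments[ti]
            pad_num += 1
            paddock_id = f"P{pad_num:02d}"
            design_rows.append({"paddock_id": paddock_id, "block": block, "treatment": trt})
            spec = study.treatments[trt]
            zones = list(default_zones(study.base.width_m, study.base.height_m))
            if trt == "weed_strip":
                zones += strip_zones(study.base.width_m, study.base.height_m)
            bundle["zones"][paddock_id] = zones
            block_speed = float(rng.lognormal(0.0, study.block_distance_sigma)) if study.block_distance_sigma > 0 else 1.0

            for a in range(1, study.testers_per_paddock + 1):
                animal_id = f"{paddock_id}-A{a}"
                traj_parts, truth_parts = [], []
                for per in range(1, study.n_periods + 1):
                    budget = _jittered_budget(rng, spec["budget"], study.budget_day_sd)
                    day_sigma = study.distance_day_sigma
                    speed_mult = block_speed * float(rng.lognormal(0.0, day_sigma)) if day_sigma > 0 else block_speed
                    v_travel = calibrate_travel_speed(budget, spec["distance_m"]) * speed_mult
                    states = default_states()
                    states["traveling"] = replace(states["traveling"], speed_m_per_min=v_travel)
                    start = pd.Timestamp(study.base.start_time) + pd.Timedelta(
                        days=(per - 1) * (study.days_per_period + study.period_gap_days)
                    )
                    cfg = replace(
                        study.base,
                        zones=zones,
                        n_days=study.days_per_period,
                        states=states,
                        target_budget=budget,
                        start_time=str(start),
                        animal_id=animal_id,
                        paddock_id=paddock_id,
                    )
                    traj, truth = simulate_trajectory(cfg, seed=rng.integers(2**31 - 1))
                    traj.period = f"period{per}"
                    traj_parts.append(traj)
                    truth_parts.append(truth)
                bundle["trajectories"].append(traj_parts)
                bundle["truths"].append(truth_parts)

    design = pd.DataFrame(design_rows)
    bundle["design"] = design
    period_starts = {
        f"period{per}": str(
            pd.Timestamp(study.base.start_time)
            + pd.Timedelta(days=(per - 1) * (study.days_per_period + study.period_gap_days))
        )
        for per in range(1, study.n_periods + 1)
    }
    bundle["period_starts"] = period_starts

    if out_dir is not None:
        _write_bundle(bundle, study, out_dir)
    return bundle


def _write_bundle(bundle, study: StudyConfig, out_dir) -> None:
    import os

    import yaml

    from grazetrack.geometry import zones_to_geojson

    os.makedirs(out_dir, exist_ok=True)
    bundle["design"].to_csv(os.path.join(out_dir, "design.csv"), index=False)
    with open(os.path.join(out_dir, "design.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "paddocks": bundle["design"].to_dict("records"),
                "period_starts": bundle["period_starts"],
                "days_per_period": study.days_per_period,
            },
            fh,
        )
    boundary = Zone("paddock_boundary", box(0, 0, study.base.width_m, study.base.height_m))
    for paddock_id, zones in bundle["zones"].items():
        zones_to_geojson([boundary] + zones, os.path.join(out_dir, f"zones_{paddock_id}.geojson"))
    truth_rows = []
    for traj_parts, truth_parts in zip(bundle["trajectories"], bundle["truths"]):
        for traj, truth in zip(traj_parts, truth_parts):
            traj.to_csv(os.path.join(out_dir, f"collar_{traj.animal_id}_{traj.period}.csv"))
            tb = truth.daily_budget()
            td = truth.daily_distance()
            tb["distance_m"] = td.to_numpy()
            tb.insert(0, "animal_id", traj.animal_id)
            tb.insert(1, "period", traj.period)
            truth_rows.append(tb)
    pd.concat(truth_rows, ignore_index=True).to_csv(os.path.join(out_dir, "ground_truth_daily.csv"), index=False)


# ----------------------------------------------------- response-level design

def simulate_study_responses(
    treatment_means,
    n_sims: int = 1,
    n_blocks: int = 4,
    n_periods: int = 5,
    block_sd: float = 200.0,
    resid_sd: float = 1000.0,
    rng=None,
) -> np.ndarray:
    """Draw paddock x period cell responses for the RCBD design directly.

    Shape (n_sims, n_treatments, n_blocks, n_periods).  Used for ANOVA
    type-I-error and power calibration, where resimulating full GPS tracks
    per replicate would add nothing: the ANOVA consumes only cell values.
    ``resid_sd`` defaults to 1000 m/day, ~20% CV of the observed daily
    distances — a realistic paddock-period dispersion.
    """
    rng = np.random.default_rng(rng)
    mu = np.asarray(treatment_means, float)[None, :, None, None]
    a = mu.shape[1]
    blocks = rng.normal(0.0, block_sd, (n_sims, 1, n_blocks, 1))
    eps = rng.normal(0.0, resid_sd, (n_sims, a, n_blocks, n_periods))
    return mu + blocks + eps


# ------------------------------------------------------------ bias experiment

def bias_experiment(
    config: SimulationConfig,
    noise_grid=(0.0, 2.0, 5.0, 10.0),
    interval_grid=(1, 10, 60, 300, 600),
    n_reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-estimation bias vs GPS noise and sampling interval.

    For each replicate a noiseless track is simulated once; the noise grid
    re-applies the GPS error model to the same true path, the interval grid
    resamples the noiseless track.  Bias is estimated minus true daily
    distance: positive under measurement error (noise), negative under
    interpolation error (coarse sampling of sinuous paths).
    """
    from grazetrack.trajectory_metrics import daily_distance, resample, step_metrics

    rng = np.random.default_rng(seed)
    base = replace(config, gps_noise_sd_m=0.0, dropout_prob=0.0)
    rows = []
    for rep in range(n_reps):
        traj, truth = simulate_trajectory(base, seed=rng.integers(2**31 - 1))
        true_d = float(truth.daily_distance().sum())
        x, y = traj.xy
        for sd in noise_grid:
            xo, yo = apply_gps_error(x, y, sd, config.noise_corr_time_s, config.quantize_m, config.fix_rate_hz, rng)
            noisy = traj.with_fixes(traj.fixes.assign(x=xo, y=yo))
            est = daily_distance(step_metrics(noisy, max_gap_s=np.inf))
            rows.append({"kind": "noise", "level": sd, "rep": rep, "true_m": true_d, "estimate_m": est, "bias_m": est - true_d})
        for iv in interval_grid:
            thin = resample(traj, iv)
            est = daily_distance(step_metrics(thin, max_gap_s=np.inf))
            rows.append({"kind": "interval", "level": iv, "rep": rep, "true_m": true_d, "estimate_m": est, "bias_m": est - true_d})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- climate

def simulate_climate(n_days: int, seed=0, mean_tdb_c: float = 26.5, sd_tdb_c: float = 1.5,
                     mean_rh_pct: float = 80.0, sd_rh_pct: float = 7.0,
                     start_date: str = "2022-07-12") -> pd.DataFrame:
    """Daily summer climate records (Gulf-coast defaults): AR(1) day-to-day
    persistence in dry-bulb temperature and relative humidity."""
    rng = np.random.default_rng(seed)
    phi = 0.5
    innov_t = rng.normal(0.0, sd_tdb_c * math.sqrt(1 - phi**2), n_days)
    innov_h = rng.normal(0.0, sd_rh_pct * math.sqrt(1 - phi**2), n_days)
    t = np.empty(n_days)
    h = np.empty(n_days)
    t[0] = mean_tdb_c + rng.normal(0.0, sd_tdb_c)
    h[0] = mean_rh_pct + rng.normal(0.0, sd_rh_pct)
    for i in range(1, n_days):
        t[i] = mean_tdb_c + phi * (t[i - 1] - mean_tdb_c) + innov_t[i]
        h[i] = mean_rh_pct + phi * (h[i - 1] - mean_rh_pct) + innov_h[i]
    h = np.clip(h, 40.0, 100.0)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    return pd.DataFrame({"date": dates, "tdb_c": t, "rh_pct": h})
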