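"""Shared fixtures: synthetic trajectories and small study trees.

All fixtures are generated programmatically at test time with fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from grazetrack.gps_io import Trajectory
from grazetrack.synthetic_herd import SimulationConfig, StudyConfig, simulate_study, simulate_trajectory


def make_traj(x, y, t0="2022-07-12T00:00:00Z", dt_s=1.0, animal_id="A1", paddock_id="P1") -> Trajectory:
    """Planar trajectory from coordinate arrays at a constant fix interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    times = pd.Timestamp(t0) + pd.to_timedelta(np.arange(len(x)) * dt_s, unit="s")
    return Trajectory(
        fixes=pd.DataFrame({"time": times, "x": x, "y": y}),
        crs_state="planar",
        animal_id=animal_id,
        paddock_id=paddock_id,
    )


@pytest.fixture(scope="session")
def clean_sim():
    """One noiseless 4 h deployment with the (85, 9, 6) design budget."""
    cfg = SimulationConfig(
        target_budget=(85.0, 9.0, 6.0), gps_noise_sd_m=0.0, n_days=1, day_seconds=4 * 3600
    )
    traj, truth = simulate_trajectory(cfg, seed=11)
    return cfg, traj, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Same design with the default 5 m collar error model."""
    cfg = SimulationConfig(
        target_budget=(85.0, 9.0, 6.0), gps_noise_sd_m=5.0, n_days=1, day_seconds=4 * 3600
    )
    traj, truth = simulate_trajectory(cfg, seed=11)
    return cfg, traj, truth


@pytest.fixture(scope="session")
def study_tree(tmp_path_factory):
    """A reduced-scale full study file tree (12 paddocks x 2 testers,
    2 periods of one 1 h 'day'), written the way the simulator emits it."""
    out = tmp_path_factory.mktemp("study")
    base = SimulationConfig(day_seconds=3600, gps_noise_sd_m=0.0)
    study = StudyConfig(base=base, n_periods=2, days_per_period=1, seed=5)
    bundle = simulate_study(study, out_dir=str(out))
    return out, study, bundle
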