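#!/usr/bin/env python
"""Summer climate simulation and period-mean THI summary.

Generates daily dry-bulb temperature and relative humidity for the
deployment window and reports per-period THI means, written to
results/climate/.
"""

import pathlib

import pandas as pd

from grazetrack.environment import period_climate_summary
from grazetrack.synthetic_herd import simulate_climate

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "climate"

if __name__ == "__main__":
    climate = simulate_climate(n_days=110, seed=2022)
    starts = {
        f"period{i+1}": climate["date"].iloc[0] + pd.Timedelta(days=22 * i) for i in range(5)
    }
    summary = period_climate_summary(climate, starts, period_len_days=21)
    OUT.mkdir(parents=True, exist_ok=True)
    climate.to_csv(OUT / "daily_climate.csv", index=False)
    summary.to_csv(OUT / "period_thi.csv", index=False)
    print(summary.round(2).to_string(index=False))
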