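"""Temperature–humidity index (THI) and daily climate summaries.

THI combines dry-bulb temperature and relative humidity into a single
heat-stress indicator for cattle:

    THI = 1.8*Tdb + 32 - (0.55 - 0.0055*RH) * (1.8*Tdb - 26.8)

with Tdb in deg C and RH in percent.  At RH = 100 the humidity correction
vanishes and THI reduces to the Fahrenheit temperature; at
Tdb = 26.8/1.8 ~= 14.89 deg C the index is independent of humidity.
Values of 74-79 correspond to light heat-stress impact on beef cattle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Tdb (deg C) at which THI is independent of RH
THI_PIVOT_C = 26.8 / 1.8


def thi(tdb_c, rh_pct):
    """Temperature–humidity index from dry-bulb deg C and RH percent."""
    tdb = np.asarray(tdb_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must be within [0, 100] percent")
    out = 1.8 * tdb + 32.0 - (0.55 - 0.0055 * rh) * (1.8 * tdb - 26.8)
    if out.ndim == 0:
        return float(out)
    return out


def read_climate_csv(path, date_col: str = "date", tdb_col: str = "tdb_c", rh_col: str = "rh_pct") -> pd.DataFrame:
    """Read a climate CSV (date, dry-bulb deg C, RH %) and append THI."""
    df = pd.read_csv(path, parse_dates=[date_col])
    df = df.rename(columns={date_col: "date", tdb_col: "tdb_c", rh_col: "rh_pct"})
    df["thi"] = thi(df["tdb_c"].to_numpy(), df["rh_pct"].to_numpy())
    return df


def period_climate_summary(climate: pd.DataFrame, period_starts, period_len_days: int = 21) -> pd.DataFrame:
    """Mean Tdb, RH, and THI per evaluation period.

    ``period_starts`` maps period label -> start date; each period spans
    ``period_len_days`` days, the collar deployment length.
    """
    if "thi" not in climate.columns:
        climate = climate.assign(thi=thi(climate["tdb_c"].to_numpy(), climate["rh_pct"].to_numpy()))
    rows = []
    for label, start in dict(period_starts).items():
        start = pd.Timestamp(start)
        end = start + pd.Timedelta(days=period_len_days)
        sel = climate[(climate["date"] >= start) & (climate["date"] < end)]
        rows.append(
            {
                "period": label,
                "n_days": len(sel),
                "mean_tdb_c": float(sel["tdb_c"].mean()),
                "mean_rh_pct": float(sel["rh_pct"].mean()),
                "mean_thi": float(sel["thi"].mean()),
            }
        )
    return pd.DataFrame(rows)
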