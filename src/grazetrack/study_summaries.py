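"""Treatment x period study summaries and fixed-effects RCBD ANOVA.

The study design is a randomized complete block design: three weed
encroachment treatments (weed_free, weed_strip, weed_infested), each
appearing once in each of four blocks, observed over repeated 21-day
evaluation periods with two tester animals per paddock.  Animal-day metrics
are averaged to paddock-days (the testers), then to paddock x period cells.
The analysis model is

    Y_ijk = mu + tau_i + beta_j + t_k + (tau x t)_ik + eps_ijk

with treatment tau, block beta, period t, their interaction, and residual
error; the classical balanced sums-of-squares decomposition is computed from
scratch and F ratios are tested against the residual mean square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TREATMENTS = ("weed_free", "weed_strip", "weed_infested")


# ---------------------------------------------------------------- aggregation

def paddock_daily_means(animal_day_metrics: pd.DataFrame, value_cols=None) -> pd.DataFrame:
    """Average each metric across the two tester animals per paddock-day.

    Rows where only one tester reported are kept but flagged
    ``incomplete=True`` rather than silently averaged as if complete.
    """
    df = animal_day_metrics
    if value_cols is None:
        value_cols = [c for c in df.columns if df[c].dtype.kind in "fi" and c not in ("excluded",)]
    g = df.groupby(["paddock_id", "date"], sort=True)
    out = g[list(value_cols)].mean().reset_index()
    out["n_testers"] = g["animal_id"].nunique().to_numpy()
    out["incomplete"] = out["n_testers"] < 2
    return out


def attach_design(paddock_days: pd.DataFrame, design: pd.DataFrame, period_starts=None, period_len_days: int = 21) -> pd.DataFrame:
    """Join block/treatment labels (and optionally period labels from dates).

    ``design`` has columns paddock_id, block, treatment.  If
    ``period_starts`` (period -> start date) is given, each row's date is
    assigned to the period window containing it.
    """
    out = paddock_days.merge(design[["paddock_id", "block", "treatment"]], on="paddock_id", how="left")
    if out["treatment"].isna().any():
        missing = out.loc[out["treatment"].isna(), "paddock_id"].unique()
        raise ValueError(f"paddocks missing from design table: {list(missing)}")
    if period_starts is not None:
        starts = sorted((pd.Timestamp(v), k) for k, v in dict(period_starts).items())
        dates = pd.to_datetime(out["date"])
        labels = np.full(len(out), None, dtype=object)
        for start, label in starts:
            in_window = (dates >= start) & (dates < start + pd.Timedelta(days=period_len_days))
            labels[in_window.to_numpy()] = label
        out["period"] = labels
    return out


def treatment_period_table(paddock_days: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Cell means per treatment x period (balanced least-squares = arithmetic
    means), in the layout of the study's summary tables."""
    cells = (
        paddock_days.groupby(["treatment", "period"], sort=True)[value_col]
        .mean()
        .unstack("period")
    )
    cells["treatment_mean"] = cells.mean(axis=1)
    return cells.reset_index()


# ---------------------------------------------------------------- RCBD ANOVA

@dataclass
class AnovaResult:
    """Classical ANOVA table for the RCBD model with repeated periods."""

    table: pd.DataFrame  # index: effect; columns: ss, df, ms, F, p
    cell_means: pd.DataFrame  # treatment x period means
    treatment_means: pd.Series
    sem: float  # standard error of a treatment mean, from residual MS
    letters: dict = field(default_factory=dict)  # treatment -> grouping letter(s)

    @property
    def p_treatment(self) -> float:
        return float(self.table.loc["treatment", "p"])


def _effect_letters(means: pd.Series, se_diff: float, df_resid: int, alpha: float = 0.05) -> dict:
    """Compact letter display from pairwise t tests on the residual MS."""
    names = list(means.sort_values(ascending=False).index)
    sig = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            tval = abs(means[a] - means[b]) / se_diff
            p = 2 * stats.t.sf(tval, df_resid)
            sig[(a, b)] = p < alpha
    # greedy grouping: walk the sorted means, start a new letter when a
    # significant break occurs
    letters = {n: "" for n in names}
    groups = []
    for n in names:
        placed = False
        for g in groups:
            if all(not sig.get((min(m, n, key=names.index), max(m, n, key=names.index)), False) for m in g):
                g.append(n)
                placed = True
        if not placed:
            groups.append([n])
    for gi, g in enumerate(groups):
        ch = chr(ord("a") + gi)
        for n in g:
            letters[n] += ch
    return letters


def rcbd_anova(data: pd.DataFrame, value_col: str = "value", alpha: float = 0.05) -> AnovaResult:
    """Fixed-effects ANOVA for a balanced RCBD with repeated periods.

    ``data`` needs columns treatment, block, period, and ``value_col`` with
    exactly one observation per treatment x block x period cell.  Raises on
    missing cells (no imputation).
    """
    df = data.copy()
    trts = sorted(df["treatment"].unique())
    blocks = sorted(df["block"].unique())
    periods = sorted(df["period"].unique())
    a, b, p = len(trts), len(blocks), len(periods)
    if len(df) != a * b * p:
        raise ValueError(f"unbalanced design: {len(df)} rows, expected {a * b * p}")

    wide = df.set_index(["treatment", "block", "period"])[value_col].unstack(["block", "period"])
    wide = wide.reindex(index=trts, columns=pd.MultiIndex.from_product([blocks, periods]))
    y = wide.to_numpy().reshape(a, b, p)
    if np.isnan(y).any():
        raise ValueError("missing cells in design")

    grand = y.mean()
    m_t = y.mean(axis=(1, 2))
    m_b = y.mean(axis=(0, 2))
    m_p = y.mean(axis=(0, 1))
    m_tp = y.mean(axis=1)

    ss_total = ((y - grand) ** 2).sum()
    ss_t = b * p * ((m_t - grand) ** 2).sum()
    ss_b = a * p * ((m_b - grand) ** 2).sum()
    ss_p = a * b * ((m_p - grand) ** 2).sum()
    ss_tp = b * ((m_tp - m_t[:, None] - m_p[None, :] + grand) ** 2).sum()
    ss_e = ss_total - ss_t - ss_b - ss_p - ss_tp

    df_t, df_b, df_p = a - 1, b - 1, p - 1
    df_tp = (a - 1) * (p - 1)
    df_e = a * b * p - 1 - df_t - df_b - df_p - df_tp

    rows = {}
    ms_e = ss_e / df_e
    for name, ss, dfree in (
        ("treatment", ss_t, df_t),
        ("block", ss_b, df_b),
        ("period", ss_p, df_p),
        ("treatment:period", ss_tp, df_tp),
    ):
        ms = ss / dfree
        F = ms / ms_e
        rows[name] = {"ss": ss, "df": dfree, "ms": ms, "F": F, "p": stats.f.sf(F, dfree, df_e)}
    rows["residual"] = {"ss": ss_e, "df": df_e, "ms": ms_e, "F": np.nan, "p": np.nan}
    rows["total"] = {"ss": ss_total, "df": a * b * p - 1, "ms": np.nan, "F": np.nan, "p": np.nan}
    table = pd.DataFrame(rows).T

    cell_means = pd.DataFrame(m_tp, index=trts, columns=periods)
    trt_means = pd.Series(m_t, index=trts)
    sem = float(np.sqrt(ms_e / (b * p)))
    se_diff = float(np.sqrt(2 * ms_e / (b * p)))
    letters = _effect_letters(trt_means, se_diff, int(df_e), alpha)

    return AnovaResult(table=table, cell_means=cell_means, treatment_means=trt_means, sem=sem, letters=letters)


def treatment_F_pvalues(y: np.ndarray) -> np.ndarray:
    """Vectorized treatment-effect p-values for many simulated designs.

    ``y`` has shape (n_sims, a, b, p) with one observation per cell; returns
    the treatment F-test p-value per simulation.  Used for type-I error and
    power calibration of :func:`rcbd_anova` (identical SS decomposition,
    batched).
    """
    n, a, b, p = y.shape
    grand = y.mean(axis=(1, 2, 3), keepdims=True)
    m_t = y.mean(axis=(2, 3), keepdims=True)
    m_b = y.mean(axis=(1, 3), keepdims=True)
    m_p = y.mean(axis=(1, 2), keepdims=True)
    m_tp = y.mean(axis=2, keepdims=True)

    ss_total = ((y - grand) ** 2).sum(axis=(1, 2, 3))
    ss_t = b * p * ((m_t - grand) ** 2).sum(axis=(1, 2, 3))
    ss_b = a * p * ((m_b - grand) ** 2).sum(axis=(1, 2, 3))
    ss_p = a * b * ((m_p - grand) ** 2).sum(axis=(1, 2, 3))
    ss_tp = b * ((m_tp - m_t - m_p + grand) ** 2).sum(axis=(1, 2, 3))
    ss_e = ss_total - ss_t - ss_b - ss_p - ss_tp

    df_t = a - 1
    df_e = a * b * p - 1 - (a - 1) - (b - 1) - (p - 1) - (a - 1) * (p - 1)
    F = (ss_t / df_t) / (ss_e / df_e)
    return stats.f.sf(F, df_t, df_e)


# ------------------------------------------------------- derived statistics

def percent_change(a: float, b: float) -> float:
    """Percent change of ``a`` relative to baseline ``b``: 100*(a-b)/b."""
    if b == 0:
        raise ValueError("baseline is zero")
    return 100.0 * (a - b) / b


def cross_treatment_mean(values) -> float:
    """Arithmetic mean across treatments (one value per treatment)."""
    v = np.asarray(values, dtype=float)
    return float(v.mean())


def frac_to_hours(pct_of_day: float) -> float:
    """Convert a percent-of-day occupancy to hours per day."""
    if not (0 <= pct_of_day <= 100):
        raise ValueError("percent of day must be in [0, 100]")
    return pct_of_day / 100.0 * 24.0


def total_herbage(component_masses) -> float:
    """Total herbage mass: sum of component masses (kg DM/ha)."""
    v = np.asarray(component_masses, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative herbage mass")
    return float(v.sum())
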