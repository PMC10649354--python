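"""Aggregation, RCBD ANOVA against an independent regression oracle, and
derived study statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grazetrack.study_summaries import (
    TREATMENTS,
    attach_design,
    cross_treatment_mean,
    frac_to_hours,
    paddock_daily_means,
    percent_change,
    rcbd_anova,
    total_herbage,
    treatment_F_pvalues,
    treatment_period_table,
)
from grazetrack.synthetic_herd import simulate_study_responses


# ----------------------------------------------------------------- fixtures

def make_balanced(rng, a=3, b=4, p=5, treatment_effects=None, sd=1.0, mu=100.0):
    """One balanced RCBD data frame with known effects."""
    trts = list(TREATMENTS)[:a]
    rows = []
    beta = rng.normal(0, 1, b)
    gamma = rng.normal(0, 1, p)
    for i, trt in enumerate(trts):
        tau = 0.0 if treatment_effects is None else treatment_effects[i]
        for j in range(b):
            for k in range(p):
                rows.append(
                    {
                        "treatment": trt,
                        "block": f"B{j+1}",
                        "period": f"P{k+1}",
                        "value": mu + tau + beta[j] + gamma[k] + rng.normal(0, sd),
                    }
                )
    return pd.DataFrame(rows)


def anova_oracle_ss(df):
    """Independent sums of squares via sequential indicator regression
    (type-I SS are type-III here because the design is balanced)."""
    y = df["value"].to_numpy()
    n = len(y)

    def dummies(col):
        return pd.get_dummies(df[col], drop_first=True, dtype=float).to_numpy()

    t = dummies("treatment")
    b = dummies("block")
    p = dummies("period")
    tp = np.einsum("ni,nj->nij", t, p).reshape(n, -1)

    def rss(X):
        X = np.column_stack([np.ones(n)] + list(X))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss0 = rss([])
    rss_t = rss([t])
    rss_tb = rss([t, b])
    rss_tbp = rss([t, b, p])
    rss_full = rss([t, b, p, tp])
    return {
        "treatment": rss0 - rss_t,
        "block": rss_t - rss_tb,
        "period": rss_tb - rss_tbp,
        "treatment:period": rss_tbp - rss_full,
        "residual": rss_full,
        "total": rss0,
    }


# -------------------------------------------------------------- aggregation

def test_paddock_daily_means_average_testers():
    df = pd.DataFrame(
        {
            "paddock_id": ["P01"] * 2 + ["P02"] * 2,
            "animal_id": ["P01-A1", "P01-A2", "P02-A1", "P02-A2"],
            "date": ["2022-07-12"] * 4,
            "distance_m": [5000.0, 6000.0, 4000.0, 4400.0],
        }
    )
    out = paddock_daily_means(df, value_cols=["distance_m"])
    assert out.loc[out["paddock_id"] == "P01", "distance_m"].iloc[0] == 5500.0
    assert not out["incomplete"].any()


def test_single_tester_day_flagged_incomplete():
    df = pd.DataFrame(
        {
            "paddock_id": ["P01", "P01", "P01"],
            "animal_id": ["P01-A1", "P01-A2", "P01-A1"],
            "date": ["2022-07-12", "2022-07-12", "2022-07-13"],
            "distance_m": [5000.0, 6000.0, 5200.0],
        }
    )
    out = paddock_daily_means(df, value_cols=["distance_m"]).set_index("date")
    assert not out.loc["2022-07-12", "incomplete"]
    assert out.loc["2022-07-13", "incomplete"]
    assert out.loc["2022-07-13", "distance_m"] == 5200.0


def test_attach_design_joins_and_labels_periods():
    days = pd.DataFrame(
        {
            "paddock_id": ["P01", "P01"],
            "date": pd.to_datetime(["2022-07-12", "2022-08-03"]),
            "distance_m": [5000.0, 5100.0],
        }
    )
    design = pd.DataFrame(
        {"paddock_id": ["P01"], "block": ["B1"], "treatment": ["weed_free"]}
    )
    out = attach_design(days, design, period_starts={"P1": "2022-07-12", "P2": "2022-08-03"})
    assert out["treatment"].tolist() == ["weed_free", "weed_free"]
    assert out["period"].tolist() == ["P1", "P2"]


def test_attach_design_missing_paddock_errors():
    days = pd.DataFrame({"paddock_id": ["P99"], "date": ["2022-07-12"], "v": [1.0]})
    design = pd.DataFrame({"paddock_id": ["P01"], "block": ["B1"], "treatment": ["weed_free"]})
    with pytest.raises(ValueError):
        attach_design(days, design)


def test_treatment_period_table_layout():
    means = {"weed_free": 4482.0 + 1175.0, "weed_strip": 4482.0 + 597.0, "weed_infested": 4482.0}
    cells = pd.DataFrame(
        [
            {"treatment": trt, "period": f"P{k+1}", "distance_m": m}
            for trt, m in means.items()
            for k in range(5)
        ]
    )
    out = treatment_period_table(cells, "distance_m")
    assert set(out["treatment"]) == set(TREATMENTS)
    wide = out.set_index("treatment")
    # treatment means recover the designed daily travel distances
    assert wide.loc["weed_free", "treatment_mean"] == pytest.approx(4482 + 1175, abs=1e-6)
    assert wide.loc["weed_strip", "treatment_mean"] == pytest.approx(4482 + 597, abs=1e-6)
    assert wide.loc["weed_infested", "treatment_mean"] == pytest.approx(4482.0, abs=1e-6)


# ------------------------------------------------------------------- ANOVA

def test_anova_ss_match_regression_oracle():
    rng = np.random.default_rng(41)
    df = make_balanced(rng, treatment_effects=(0.0, 2.0, 5.0), sd=3.0)
    res = rcbd_anova(df)
    want = anova_oracle_ss(df)
    for effect, ss in want.items():
        assert res.table.loc[effect, "ss"] == pytest.approx(ss, rel=1e-9), effect
    # degrees of freedom for a=3, b=4, p=5
    assert res.table.loc["treatment", "df"] == 2
    assert res.table.loc["residual", "df"] == 42
    assert res.sem == pytest.approx(np.sqrt(res.table.loc["residual", "ms"] / 20))


def test_anova_total_ss_identity():
    rng = np.random.default_rng(42)
    df = make_balanced(rng, sd=2.0)
    res = rcbd_anova(df)
    parts = res.table.loc[["treatment", "block", "period", "treatment:period", "residual"], "ss"].sum()
    assert parts == pytest.approx(res.table.loc["total", "ss"], rel=1e-12)


def test_anova_row_permutation_invariance():
    rng = np.random.default_rng(43)
    df = make_balanced(rng, treatment_effects=(0.0, 1.0, 2.0), sd=1.5)
    res1 = rcbd_anova(df)
    res2 = rcbd_anova(df.sample(frac=1.0, random_state=7).reset_index(drop=True))
    pd.testing.assert_frame_equal(res1.table, res2.table)


def test_anova_rejects_unbalanced_and_missing():
    rng = np.random.default_rng(44)
    df = make_balanced(rng)
    with pytest.raises(ValueError):
        rcbd_anova(df.iloc[:-1])
    dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError):
        rcbd_anova(dup)


def test_anova_detects_injected_shift_with_letters():
    rng = np.random.default_rng(45)
    df = make_balanced(rng, treatment_effects=(10.0, 0.0, 0.0), sd=1.0)
    res = rcbd_anova(df)
    assert res.p_treatment < 0.001
    assert res.letters["weed_free"] != res.letters["weed_infested"]


def test_vectorized_pvalues_match_single_anova():
    rng = np.random.default_rng(46)
    df = make_balanced(rng, treatment_effects=(0.0, 1.0, 3.0), sd=2.0)
    res = rcbd_anova(df)
    y = (
        df.set_index(["treatment", "block", "period"])["value"]
        .unstack(["block", "period"])
        .to_numpy()
        .reshape(1, 3, 4, 5)
    )
    assert treatment_F_pvalues(y)[0] == pytest.approx(res.p_treatment, rel=1e-12)


def test_null_pvalues_are_uniformish():
    rng = np.random.default_rng(47)
    y = simulate_study_responses((5000.0, 5000.0, 5000.0), n_sims=400, rng=rng)
    pvals = treatment_F_pvalues(y)
    # Kolmogorov-Smirnov against U(0,1) on null p-values
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
    assert abs((pvals < 0.05).mean() - 0.05) < 0.035


# --------------------------------------------------------------- derived

def test_percent_change_example():
    assert percent_change(5657.0, 4482.0) == pytest.approx(26.2, abs=0.05)
    with pytest.raises(ValueError):
        percent_change(1.0, 0.0)


def test_cross_treatment_means_example():
    assert cross_treatment_mean([85.1, 87.8, 88.8]) == pytest.approx(87.2, abs=0.05)
    assert cross_treatment_mean([8.9, 7.2, 6.6]) == pytest.approx(7.6, abs=0.05)
    assert cross_treatment_mean([6.0, 4.9, 4.7]) == pytest.approx(5.2, abs=0.05)


def test_frac_to_hours_examples():
    assert frac_to_hours(21.0) == pytest.approx(5.04)
    assert frac_to_hours(11.0) == pytest.approx(2.64)
    assert frac_to_hours(29.1) == pytest.approx(6.984)
    with pytest.raises(ValueError):
        frac_to_hours(120.0)


def test_total_herbage_examples():
    assert total_herbage([3021.0, 2740.0]) == pytest.approx(5761.0)
    assert total_herbage([3114.0, 1024.0]) == pytest.approx(4138.0)
    with pytest.raises(ValueError):
        total_herbage([-1.0, 2.0])
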