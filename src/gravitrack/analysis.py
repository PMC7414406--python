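"""Cohort-level analysis: longitudinal models, nonparametric tests, reports.

Consumes the summary tables of the processing stage and produces the
period-comparison report (means with 95% CIs and pairwise p-values from
the compound-symmetry mixed model), the Friedman test of weekly MVPA
across periods, Spearman correlations between activity and sleep, the
guideline-compliance table, and weekly trajectory figures with sidecar
CSVs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as gstats
from .metrics import IntensityConfig, guideline_compliance
from .timeline import Period

PERIOD_ORDER = [Period.SECOND_TRIMESTER.value, Period.THIRD_TRIMESTER.value,
                Period.POSTPARTUM.value]
PERIOD_OUTCOMES = {
    "steps": "steps",
    "sleep_minutes": "sleep_minutes",
    "awake_minutes": "awake_minutes",
}


def _long_table(period: pd.DataFrame, column: str) -> pd.DataFrame:
    df = period[["participant_id", "period", column]].rename(
        columns={"period": "level", column: "value"})
    return df.dropna(subset=["value"])


def period_models(period: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Fit the compound-symmetry model per outcome over the three periods."""
    out = {}
    for name, column in PERIOD_OUTCOMES.items():
        table = _long_table(period, column)
        if table["level"].nunique() < 2 or table["participant_id"].nunique() < 2:
            continue
        levels = [lv for lv in PERIOD_ORDER if lv in set(table["level"])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[name] = gstats.fit_cs_model(table, levels=levels, alpha=alpha)
    return out


def tidy_model_table(models: dict) -> pd.DataFrame:
    """Flatten fitted models into one tidy report table."""
    rows = []
    for outcome, res in models.items():
        for _, r in res.means.iterrows():
            rows.append({"outcome": outcome, "term": r["level"],
                         "kind": "mean", "estimate": r["estimate"],
                         "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                         "p": np.nan})
        for _, r in res.contrasts.iterrows():
            rows.append({"outcome": outcome,
                         "term": f"{r['level_a']} - {r['level_b']}",
                         "kind": "contrast", "estimate": r["estimate"],
                         "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                         "p": r["p"]})
        rows.append({"outcome": outcome, "term": "time", "kind": "overall",
                     "estimate": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p": res.overall_p})
    return pd.DataFrame(rows)


def weekly_steps_model(weekly: pd.DataFrame, alpha: float = 0.05):
    """Compound-symmetry model of mean daily steps over gestational weeks."""
    wk = weekly[(weekly["week_type"] == "gestational")
                & weekly["mean_daily_steps"].notna()]
    table = wk[["participant_id", "week_number", "mean_daily_steps"]].rename(
        columns={"week_number": "level", "mean_daily_steps": "value"})
    levels = sorted(table["level"].unique())
    if len(levels) < 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gstats.fit_cs_model(table, levels=levels, alpha=alpha)


def mvpa_friedman(period: pd.DataFrame) -> dict | None:
    """Friedman test of weekly MVPA minutes across the three periods."""
    wide = period.pivot_table(index="participant_id", columns="period",
                              values="mvpa_weekly", aggfunc="first")
    wide = wide.reindex(columns=[c for c in PERIOD_ORDER if c in wide.columns])
    wide = wide.dropna()
    if len(wide) < 2 or wide.shape[1] < 2:
        return None
    return gstats.friedman_test(wide)


def steps_sleep_spearman(period: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of participant mean steps vs sleep per period."""
    rows = []
    for p in PERIOD_ORDER:
        sub = period[period["period"] == p].dropna(
            subset=["steps", "sleep_minutes"])
        if len(sub) >= 3:
            r = gstats.spearman(sub["steps"], sub["sleep_minutes"])
            rows.append({"period": p, **r})
    return pd.DataFrame(rows)


def weekly_trajectories(weekly: pd.DataFrame) -> pd.DataFrame:
    """Cohort weekly mean +/- SD of steps, sleep, resting HR and MVPA."""
    rows = []
    for (wtype, wnum), grp in weekly.groupby(["week_type", "week_number"]):
        for col in ("mean_daily_steps", "mean_sleep_minutes",
                    "mean_awake_minutes", "resting_hr", "mvpa_weekly"):
            vals = grp[col].dropna()
            if not len(vals):
                continue
            rows.append({"week_type": wtype, "week_number": wnum,
                         "outcome": col, "mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                         "n": int(len(vals))})
    return pd.DataFrame(rows)


def analyze_cohort(processed: dict, intensity: IntensityConfig | None = None,
                   alpha: float = 0.05) -> dict:
    intensity = intensity or IntensityConfig()
    period = processed["period"]
    weekly = processed["weekly"]
    models = period_models(period, alpha=alpha) if len(period) else {}
    out = {
        "period_models": models,
        "period_report": tidy_model_table(models) if models else pd.DataFrame(),
        "weekly_steps_model": weekly_steps_model(weekly, alpha=alpha)
            if len(weekly) else None,
        "friedman_mvpa": mvpa_friedman(period) if len(period) else None,
        "spearman": steps_sleep_spearman(period) if len(period)
            else pd.DataFrame(),
        "compliance": guideline_compliance(weekly, intensity)
            if len(weekly) else {"weekly": pd.DataFrame(),
                                 "by_period": pd.DataFrame()},
        "trajectories": weekly_trajectories(weekly) if len(weekly)
            else pd.DataFrame(),
    }
    return out


# ---------------------------------------------------------------------------
# figures


def plot_trajectories(trajectories: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Weekly mean +/- SD band plots with data sidecar CSVs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    labels = {
        "mean_daily_steps": ("Daily steps", "steps/day"),
        "mean_sleep_minutes": ("Sleep", "min/night"),
        "mean_awake_minutes": ("Awake", "min/night"),
        "resting_hr": ("Resting heart rate", "bpm"),
        "mvpa_weekly": ("MVPA", "min/week"),
    }
    for outcome, (title, unit) in labels.items():
        sub = trajectories[trajectories["outcome"] == outcome]
        if not len(sub):
            continue
        fig, ax = plt.subplots(figsize=(7, 3.5))
        for wtype, color in (("gestational", "tab:blue"),
                             ("postpartum", "tab:orange")):
            s = sub[sub["week_type"] == wtype].sort_values("week_number")
            if not len(s):
                continue
            x = s["week_number"] if wtype == "gestational" \
                else s["week_number"] + 42
            ax.plot(x, s["mean"], color=color, label=wtype)
            ax.fill_between(x, s["mean"] - s["sd"], s["mean"] + s["sd"],
                            color=color, alpha=0.2)
        ax.set_xlabel("gestational week (postpartum offset +42)")
        ax.set_ylabel(unit)
        ax.set_title(title)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        png = outdir / f"weekly_{outcome}.png"
        fig.savefig(png, dpi=110)
        plt.close(fig)
        sub.to_csv(outdir / f"weekly_{outcome}.csv", index=False)
        written.append(png)
    return written
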