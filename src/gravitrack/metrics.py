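"""Analysis variables derived from preprocessed streams.

Daily steps, nightly sleep and awake minutes, resting heart rate
(minimum sustained 30-minute average per day), moderate-to-vigorous
physical activity (MVPA) minutes under a 10-minute-bout rule, weekly and
period aggregates, and guideline-compliance summaries.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import (PROV_MISSING, onset_night, retained_sleep,
                            steps_on_grid)
from .validity import ValidityConfig


@dataclass(frozen=True)
class IntensityConfig:
    """Parameters of the intensity-minute (MVPA) rule.

    A minute qualifies as moderate when the homogenized heart rate reaches
    ``resting + hrr_moderate_fraction * (max_hr - resting)`` (heart-rate
    reserve method, ``max_hr = 220 - age``), or — when no heart-rate value
    covers the minute — when step cadence reaches ``cadence_threshold``.
    Vigorous is analogous with ``hrr_vigorous_fraction`` and
    ``vigorous_cadence_threshold``.  Only minutes inside maximal runs of at
    least ``bout_minimum`` consecutive qualifying minutes earn intensity
    minutes, and every minute of a qualifying run counts.
    """

    bout_minimum: int = 10
    cadence_threshold: float = 100.0        # steps/min, moderate fallback
    vigorous_cadence_threshold: float = 130.0
    hrr_moderate_fraction: float = 0.40
    hrr_vigorous_fraction: float = 0.60
    max_hr_intercept: float = 220.0         # max_hr = intercept - slope*age
    max_hr_age_slope: float = 1.0
    moderate_weekly_target: float = 150.0   # min/week
    vigorous_weekly_target: float = 75.0
    count_vigorous_double: bool = False     # moderate + 2*vigorous >= 150

    def __post_init__(self) -> None:
        if not (0 < self.hrr_moderate_fraction
                < self.hrr_vigorous_fraction < 1):
            raise ValueError("need 0 < moderate fraction < vigorous fraction < 1")
        if self.bout_minimum < 1:
            raise ValueError("bout_minimum must be >= 1")

    def max_hr(self, age: float) -> float:
        return self.max_hr_intercept - self.max_hr_age_slope * age


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def percent_change(baseline: float, later: float) -> int:
    """Integer percent change from baseline, e.g. (60, 70) -> 17."""
    return round_half_away(100.0 * (later - baseline) / baseline)


# ---------------------------------------------------------------------------
# daily primitives


def daily_steps(steps: pd.Series, date: dt.date) -> int:
    """Sum of minute step counts on a calendar day; absent minutes count 0."""
    start = pd.Timestamp(date)
    end = start + pd.Timedelta(days=1)
    day = steps[(steps.index >= start) & (steps.index < end)]
    return int(day.sum())


def nightly_sleep(audited_sleep: pd.DataFrame,
                  night: dt.date) -> tuple[float, float] | tuple[None, None]:
    """Sleep and awake minutes of the night starting on calendar day ``night``.

    Sums retained (accepted/trimmed) periods attributed to the night of
    their onset, where the night of day ``d`` runs noon-to-noon (an onset
    between 12:00 on ``d`` and 12:00 the next day, so a post-midnight
    return to sleep stays with the same night).  Sleep minutes exclude the
    device-scored awake minutes.  Returns ``(None, None)`` when the night
    has no retained period — absence of a measurement, not zero sleep.
    """
    kept = retained_sleep(audited_sleep)
    if not len(kept):
        return None, None
    onsets = onset_night(kept["onset"])
    sel = kept[onsets == pd.Timestamp(night)]
    if not len(sel):
        return None, None
    duration = np.asarray(
        (pd.DatetimeIndex(sel["offset"])
         - pd.DatetimeIndex(sel["onset"])).total_seconds()) / 60.0
    awake = float(sel["awake_minutes"].sum())
    return float(duration.sum() - awake), awake


def resting_heart_rate(hr_grid: pd.DataFrame, date: dt.date,
                       window_bins: int = 2) -> float:
    """Minimum sustained heart rate on a day.

    The minimum over all rolling ``window_bins``-bin (30-minute at the
    default 15-minute grid) averages of consecutive non-missing bins within
    the 24-hour window.  NaN when no such run of bins exists.
    """
    start = pd.Timestamp(date)
    end = start + pd.Timedelta(days=1)
    day = hr_grid[(hr_grid.index >= start) & (hr_grid.index < end)]
    vals = day["value"].to_numpy()
    ok = np.isfinite(vals) & (day["provenance"].to_numpy() != PROV_MISSING)
    if len(vals) < window_bins:
        return float("nan")
    best = np.inf
    window_ok = np.ones(len(vals) - window_bins + 1, dtype=bool)
    for k in range(window_bins):
        window_ok &= ok[k:len(ok) - window_bins + 1 + k]
    if not window_ok.any():
        return float("nan")
    csum = np.concatenate([[0.0], np.cumsum(np.where(ok, vals, 0.0))])
    means = (csum[window_bins:] - csum[:-window_bins]) / window_bins
    best = means[window_ok].min()
    return float(best)


# ---------------------------------------------------------------------------
# MVPA bout rule


def bout_mask(qualifying: np.ndarray, bout_minimum: int) -> np.ndarray:
    """Minutes inside maximal qualifying runs of length >= bout_minimum.

    Pure run-length implementation of the intensity-minute rule; every
    minute of a long-enough run counts, shorter runs earn nothing.
    """
    q = np.asarray(qualifying, dtype=bool)
    if not len(q):
        return q.copy()
    padded = np.concatenate([[False], q, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    out = np.zeros(len(q), dtype=bool)
    for s, e in zip(starts, ends):
        if e - s >= bout_minimum:
            out[s:e] = True
    return out


def minute_intensity(steps: pd.Series, hr_grid: pd.DataFrame,
                     resting: float, age: float, config: IntensityConfig,
                     start: pd.Timestamp, end: pd.Timestamp,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute (moderate-or-above, vigorous) qualification over [start, end).

    Heart rate governs when a homogenized value covers the minute; the
    cadence fallback applies only to minutes without heart-rate coverage
    (device behaviour when the optical sensor is off).
    """
    n_min = int((end - start) // pd.Timedelta(minutes=1))
    cadence = steps_on_grid(steps, start, end).to_numpy().astype(float)

    hr_minutes = np.full(n_min, np.nan)
    if len(hr_grid):
        sub = hr_grid[(hr_grid.index >= start) & (hr_grid.index < end)]
        if len(sub):
            bin_width = pd.Timedelta(minutes=15) if len(hr_grid) < 2 else \
                hr_grid.index[1] - hr_grid.index[0]
            mins_per_bin = int(bin_width // pd.Timedelta(minutes=1))
            vals = np.repeat(sub["value"].to_numpy(), mins_per_bin)
            i0 = int((sub.index[0] - start) // pd.Timedelta(minutes=1))
            lo, hi = max(i0, 0), min(i0 + len(vals), n_min)
            hr_minutes[lo:hi] = vals[lo - i0:hi - i0]

    has_hr = np.isfinite(hr_minutes) & np.isfinite(resting)
    max_hr = config.max_hr(age)
    mod_thr = resting + config.hrr_moderate_fraction * (max_hr - resting)
    vig_thr = resting + config.hrr_vigorous_fraction * (max_hr - resting)

    moderate = np.where(has_hr, hr_minutes >= mod_thr,
                        cadence >= config.cadence_threshold)
    vigorous = np.where(has_hr, hr_minutes >= vig_thr,
                        cadence >= config.vigorous_cadence_threshold)
    return moderate.astype(bool), vigorous.astype(bool) & moderate.astype(bool)


def mvpa_minutes(steps: pd.Series, hr_grid: pd.DataFrame, resting: float,
                 age: float, config: IntensityConfig,
                 date: dt.date) -> tuple[int, int]:
    """Daily (moderate, vigorous) intensity minutes under the bout rule.

    Returns minutes inside counted bouts, split into moderate-only and
    vigorous; their sum is the day's MVPA minutes.
    """
    start = pd.Timestamp(date)
    end = start + pd.Timedelta(days=1)
    moderate, vigorous = minute_intensity(steps, hr_grid, resting, age,
                                          config, start, end)
    counted = bout_mask(moderate, config.bout_minimum)
    vig = int((counted & vigorous).sum())
    mod = int(counted.sum()) - vig
    return mod, vig


# ---------------------------------------------------------------------------
# aggregation


def weekly_and_period_summaries(
    daily: pd.DataFrame,
    validity_config: ValidityConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate daily summaries into weekly and period tables.

    ``daily`` carries one row per participant-day with the columns produced
    by the processing stage (steps, sleep/awake minutes, resting HR, MVPA,
    validity flags, week and period labels).  Weekly step/MVPA values
    average/sum activity-valid days in activity-valid weeks only; weekly
    sleep values average sleep-valid nights in sleep-valid weeks; period
    values average all accepted days in the period directly (no
    week-weighting), so a period mean equals the mean over the concatenated
    valid days.  A participant-period with zero valid days yields no row —
    the participant simply drops out of that period's n.
    """
    weekly_rows = []
    group_cols = ["participant_id", "week_type", "week_number"]
    for (pid, wtype, wnum), grp in daily.groupby(group_cols, sort=True):
        act_week_valid = bool(grp["activity_week_valid"].any())
        slp_week_valid = bool(grp["sleep_week_valid"].any())
        act_days = grp[grp["activity_valid"]]
        slp_days = grp[grp["sleep_valid"]]
        hr_days = grp["resting_hr"].dropna()
        row = {
            "participant_id": pid, "week_type": wtype, "week_number": wnum,
            "period": grp["period"].iloc[0],
            "activity_week_valid": act_week_valid,
            "sleep_week_valid": slp_week_valid,
            "n_valid_activity_days": int(len(act_days)),
            "n_valid_sleep_days": int(len(slp_days)),
            "mean_daily_steps": float(act_days["steps"].mean())
                if act_week_valid and len(act_days) else np.nan,
            "mvpa_moderate_weekly": float(act_days["mvpa_moderate"].sum())
                if act_week_valid and len(act_days) else np.nan,
            "mvpa_vigorous_weekly": float(act_days["mvpa_vigorous"].sum())
                if act_week_valid and len(act_days) else np.nan,
            "mean_sleep_minutes": float(slp_days["sleep_minutes"].mean())
                if slp_week_valid and len(slp_days) else np.nan,
            "mean_awake_minutes": float(slp_days["awake_minutes"].mean())
                if slp_week_valid and len(slp_days) else np.nan,
            "resting_hr": float(hr_days.mean()) if len(hr_days) else np.nan,
        }
        row["mvpa_weekly"] = (row["mvpa_moderate_weekly"]
                              + row["mvpa_vigorous_weekly"]) \
            if act_week_valid and len(act_days) else np.nan
        weekly_rows.append(row)
    weekly = pd.DataFrame(weekly_rows)

    period_rows = []
    for (pid, period), grp in daily.groupby(["participant_id", "period"],
                                            sort=True):
        act_days = grp[grp["activity_valid"]]
        slp_days = grp[grp["sleep_valid"]]
        hr_days = grp["resting_hr"].dropna()
        if not len(act_days) and not len(slp_days):
            continue
        wk = weekly[(weekly["participant_id"] == pid)
                    & (weekly["period"] == period)
                    & weekly["activity_week_valid"]]
        period_rows.append({
            "participant_id": pid, "period": period,
            "n_valid_activity_days": int(len(act_days)),
            "n_valid_sleep_days": int(len(slp_days)),
            "steps": float(act_days["steps"].mean()) if len(act_days) else np.nan,
            "sleep_minutes": float(slp_days["sleep_minutes"].mean())
                if len(slp_days) else np.nan,
            "awake_minutes": float(slp_days["awake_minutes"].mean())
                if len(slp_days) else np.nan,
            "resting_hr": float(hr_days.mean()) if len(hr_days) else np.nan,
            "mvpa_weekly": float(wk["mvpa_weekly"].mean()) if len(wk) else np.nan,
        })
    period = pd.DataFrame(period_rows)
    return weekly, period


def guideline_compliance(weekly: pd.DataFrame,
                         config: IntensityConfig) -> dict:
    """Weekly guideline flags and cohort compliance proportions.

    A week is compliant when moderate minutes reach the weekly moderate
    target (150 min) or vigorous minutes reach the vigorous target (75
    min); optionally vigorous minutes count double toward the moderate
    target.  A participant "ever met" the recommendation in a period when
    at least one of their valid weeks in that period was compliant.
    Proportions are reported as n/N with integer percent.
    """
    wk = weekly[weekly["activity_week_valid"]].copy()
    mod = wk["mvpa_moderate_weekly"].fillna(0.0)
    vig = wk["mvpa_vigorous_weekly"].fillna(0.0)
    compliant = (mod >= config.moderate_weekly_target) \
        | (vig >= config.vigorous_weekly_target)
    if config.count_vigorous_double:
        compliant |= (mod + 2.0 * vig) >= config.moderate_weekly_target
    wk["week_compliant"] = compliant

    per_period = []
    for period, grp in wk.groupby("period", sort=True):
        ever = grp.groupby("participant_id")["week_compliant"].any()
        n_ever, n_part = int(ever.sum()), int(len(ever))
        n_weeks_c, n_weeks = int(grp["week_compliant"].sum()), int(len(grp))
        per_period.append({
            "period": period,
            "participants_meeting": n_ever,
            "participants_total": n_part,
            "participants_pct": round_half_away(100.0 * n_ever / n_part)
                if n_part else 0,
            "weeks_meeting": n_weeks_c,
            "weeks_total": n_weeks,
            "weeks_pct": round_half_away(100.0 * n_weeks_c / n_weeks)
                if n_weeks else 0,
        })
    return {"weekly": wk, "by_period": pd.DataFrame(per_period)}
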