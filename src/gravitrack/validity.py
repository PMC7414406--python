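"""Day- and week-level acceptance rules deciding which data enter analysis.

Activity (step and heart-rate) data for a day are valid when the device was
worn for at least 10 awake hours (600 minutes outside retained sleep
periods); a week of activity data needs at least 4 such days.  The week of
delivery is the one exception: it is usually truncated, so any day with
awake wear counts, and one valid day validates the week.  A week of sleep
data needs at least 4 retained sleep periods on distinct onset nights.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import onset_night, retained_sleep, sleep_minute_mask
from .timeline import GestationalTimeline


@dataclass(frozen=True)
class ValidityConfig:
    min_awake_wear_minutes: int = 600      # "10 hours per day while awake"
    min_valid_days_per_week: int = 4
    min_sleep_periods_per_week: int = 4

    def __post_init__(self) -> None:
        if min(self.min_awake_wear_minutes, self.min_valid_days_per_week,
               self.min_sleep_periods_per_week) <= 0:
            raise ValueError("validity thresholds must be positive")
        if self.min_valid_days_per_week > 7:
            raise ValueError("min_valid_days_per_week cannot exceed 7")


def awake_wear_minutes(date: dt.date, wear: pd.Series,
                       audited_sleep: pd.DataFrame) -> int:
    """Worn minutes on ``date`` outside retained (accepted/trimmed) sleep."""
    start = pd.Timestamp(date)
    end = start + pd.Timedelta(days=1)
    day = wear[(wear.index >= start) & (wear.index < end)]
    if not len(day):
        return 0
    sleep_mask = sleep_minute_mask(audited_sleep, start, end)
    worn = day.reindex(pd.date_range(start, end, freq="min", inclusive="left"),
                       fill_value=False).to_numpy()
    return int((worn & ~sleep_mask).sum())


def classify_activity_day(date: dt.date, awake_wear: int,
                          config: ValidityConfig,
                          timeline: GestationalTimeline) -> dict:
    """Day-level activity validity with the delivery-week exception.

    A day is valid when awake wear reaches the threshold; during the
    delivery week any day with positive awake wear is admitted, because the
    delivery week is shorter than 7 days for almost every participant.
    """
    delivery_week = timeline.is_delivery_week(date)
    valid = awake_wear >= config.min_awake_wear_minutes
    if delivery_week and awake_wear > 0:
        valid = True
    return {
        "date": date,
        "awake_wear_minutes": int(awake_wear),
        "activity_valid": bool(valid),
        "delivery_week_flag": bool(delivery_week),
    }


def classify_activity_week(days: pd.DataFrame, config: ValidityConfig) -> bool:
    """Week validity: >=4 valid days; delivery week relaxes to >=1.

    ``days`` holds the DayValidity rows of one week (columns
    ``activity_valid`` and ``delivery_week_flag``).
    """
    n_valid = int(days["activity_valid"].sum())
    if bool(days["delivery_week_flag"].any()):
        return n_valid >= 1
    return n_valid >= config.min_valid_days_per_week


def classify_sleep_week(audited_week: pd.DataFrame,
                        config: ValidityConfig) -> bool:
    """Sleep-week validity: >=4 retained periods on distinct onset nights."""
    kept = retained_sleep(audited_week)
    if not len(kept):
        return False
    nights = onset_night(kept["onset"]).unique()
    return len(nights) >= config.min_sleep_periods_per_week


def coverage_report(daily: pd.DataFrame,
                    timelines: dict[str, GestationalTimeline]) -> pd.DataFrame:
    """Per-participant valid-day counts and percentages of possible days.

    ``daily`` must carry columns ``participant_id``, ``date``, ``segment``
    ("pregnancy"/"postpartum"), ``activity_valid``, ``sleep_valid``.  The
    possible-day denominators are the fixed window sizes of the timeline
    (203 pregnancy days for the default 13-42 week window, 28 postpartum),
    independent of the participant's actual delivery date.
    """
    rows = []
    for (pid, segment), grp in daily.groupby(["participant_id", "segment"],
                                             sort=True):
        timeline = timelines[pid]
        possible = timeline.possible_monitoring_days(segment)
        n_act = int(grp["activity_valid"].sum())
        n_slp = int(grp["sleep_valid"].sum())
        rows.append({
            "participant_id": pid,
            "segment": segment,
            "valid_activity_days": n_act,
            "valid_sleep_days": n_slp,
            "possible_days": possible,
            "activity_pct": 100.0 * n_act / possible,
            "sleep_pct": 100.0 * n_slp / possible,
        })
    return pd.DataFrame(rows)


def coverage_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Cohort median and range of valid days per segment."""
    rows = []
    for segment, grp in report.groupby("segment"):
        for kind in ("activity", "sleep"):
            days = grp[f"valid_{kind}_days"]
            rows.append({
                "segment": segment,
                "stream": kind,
                "median_days": float(days.median()),
                "min_days": int(days.min()),
                "max_days": int(days.max()),
                "median_pct": float(grp[f"{kind}_pct"].median()),
            })
    return pd.DataFrame(rows)
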