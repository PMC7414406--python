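"""End-to-end processing: raw streams -> daily/weekly/period summary tables.

Chains heart-rate homogenization, wear detection, sleep cross-checking,
the day/week validity rules and metric derivation for each participant,
and assembles cohort-level tables.  The per-day quantities are computed
with vectorized equivalents of the per-date operations in
:mod:`gravitrack.metrics`; their agreement is exercised in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics, preprocessing, validity
from .metrics import IntensityConfig
from .preprocessing import retained_sleep
from .synthetic import RawParticipantStreams
from .timeline import ParticipantProfile, Period
from .validity import ValidityConfig

MIN_PER_DAY = 1440
BINS_PER_DAY = 96


@dataclass
class ProcessOptions:
    validity: ValidityConfig = field(default_factory=ValidityConfig)
    intensity: IntensityConfig = field(default_factory=IntensityConfig)
    hr_max_gap_minutes: int = 60
    movement_fraction_threshold: float = 0.10


@dataclass
class ParticipantResult:
    profile: ParticipantProfile
    daily: pd.DataFrame
    audited_sleep: pd.DataFrame
    hr_grid: pd.DataFrame
    wear: pd.Series


def _segment(period: Period) -> str:
    if period in (Period.SECOND_TRIMESTER, Period.THIRD_TRIMESTER):
        return "pregnancy"
    if period == Period.POSTPARTUM:
        return "postpartum"
    return "out_of_window"


def process_participant(profile: ParticipantProfile, steps: pd.Series,
                        hr: pd.Series, sleep: pd.DataFrame,
                        options: ProcessOptions | None = None,
                        ) -> ParticipantResult:
    options = options or ProcessOptions()
    timeline = profile.timeline
    dates = timeline.monitored_dates()
    nd = len(dates)
    start = pd.Timestamp(dates[0])
    end = start + pd.Timedelta(days=nd)

    hr_grid = preprocessing.homogenize_heart_rate(
        hr, max_gap=pd.Timedelta(minutes=options.hr_max_gap_minutes),
        span=(start, end))
    wear = preprocessing.detect_wear(hr_grid, steps, span=(start, end))
    audited = preprocessing.cross_check_sleep(
        sleep, steps, wear,
        movement_fraction_threshold=options.movement_fraction_threshold)
    kept_sleep = retained_sleep(audited)

    worn = wear.to_numpy().reshape(nd, MIN_PER_DAY)
    sleep_mask = preprocessing.sleep_minute_mask(audited, start, end) \
        .reshape(nd, MIN_PER_DAY)
    cadence = preprocessing.steps_on_grid(steps, start, end) \
        .to_numpy().reshape(nd, MIN_PER_DAY)

    awake_wear = (worn & ~sleep_mask).sum(axis=1)
    day_steps = cadence.sum(axis=1)

    # nightly sleep attributed to the onset night
    sleep_by_night: dict[pd.Timestamp, tuple[float, float]] = {}
    if len(kept_sleep):
        dur = (pd.DatetimeIndex(kept_sleep["offset"])
               - pd.DatetimeIndex(kept_sleep["onset"])).total_seconds() / 60.0
        tmp = pd.DataFrame({
            "night": preprocessing.onset_night(kept_sleep["onset"]),
            "sleep": dur - kept_sleep["awake_minutes"].to_numpy(),
            "awake": kept_sleep["awake_minutes"].to_numpy(),
        })
        agg = tmp.groupby("night").sum()
        sleep_by_night = {ts: (row["sleep"], row["awake"])
                          for ts, row in agg.iterrows()}

    # resting heart rate: minimum 2-bin (30-minute) rolling average per day
    vals = hr_grid["value"].to_numpy().reshape(nd, BINS_PER_DAY)
    ok = np.isfinite(vals)
    pair_ok = ok[:, :-1] & ok[:, 1:]
    pair_mean = np.where(pair_ok, (vals[:, :-1] + vals[:, 1:]) / 2.0, np.inf)
    resting = np.where(pair_ok.any(axis=1), pair_mean.min(axis=1), np.nan)

    # MVPA: per-minute intensity with the day's resting HR, full-span bouts
    rest_fill = pd.Series(resting).ffill().bfill().to_numpy()
    hr_minutes = np.repeat(hr_grid["value"].to_numpy(), 15).reshape(
        nd, MIN_PER_DAY)
    rest_min = rest_fill[:, None]
    cfg = options.intensity
    max_hr = cfg.max_hr(profile.age)
    thr_mod = rest_min + cfg.hrr_moderate_fraction * (max_hr - rest_min)
    thr_vig = rest_min + cfg.hrr_vigorous_fraction * (max_hr - rest_min)
    has_hr = np.isfinite(hr_minutes) & np.isfinite(rest_min)
    moderate = np.where(has_hr, hr_minutes >= thr_mod,
                        cadence >= cfg.cadence_threshold)
    vigorous = np.where(has_hr, hr_minutes >= thr_vig,
                        cadence >= cfg.vigorous_cadence_threshold) & moderate
    counted = metrics.bout_mask(moderate.reshape(-1), cfg.bout_minimum) \
        .reshape(nd, MIN_PER_DAY)
    mvpa_vig = (counted & vigorous).sum(axis=1)
    mvpa_mod = counted.sum(axis=1) - mvpa_vig

    rows = []
    for d, date in enumerate(dates):
        period = timeline.assign_period(date)
        night = pd.Timestamp(date)
        slp = sleep_by_night.get(night)
        if timeline.delivery_date is not None and date > timeline.delivery_date:
            week_type = "postpartum"
            week_number = (timeline.postpartum_day(date) - 1) // 7 + 1
        else:
            week_type = "gestational"
            week_number = timeline.gestational_week(date)
        day_flags = validity.classify_activity_day(
            date, int(awake_wear[d]), options.validity, timeline)
        rows.append({
            "participant_id": profile.participant_id,
            "date": date,
            "segment": _segment(period),
            "period": period.value,
            "week_type": week_type,
            "week_number": int(week_number),
            "gestational_week": timeline.gestational_week(date),
            "delivery_week_flag": day_flags["delivery_week_flag"],
            "awake_wear_minutes": int(awake_wear[d]),
            "activity_day_valid": day_flags["activity_valid"],
            "steps": int(day_steps[d]),
            "sleep_minutes": slp[0] if slp else np.nan,
            "awake_minutes": slp[1] if slp else np.nan,
            "sleep_day_valid": slp is not None,
            "resting_hr": float(resting[d]),
            "mvpa_moderate": int(mvpa_mod[d]),
            "mvpa_vigorous": int(mvpa_vig[d]),
        })
    daily = pd.DataFrame(rows)

    # week-level validity
    daily["activity_week_valid"] = False
    daily["sleep_week_valid"] = False
    night_index = preprocessing.onset_night(kept_sleep["onset"]) \
        if len(kept_sleep) else pd.DatetimeIndex([])
    for (_, _), grp in daily.groupby(["week_type", "week_number"], sort=False):
        act_ok = validity.classify_activity_week(
            grp.rename(columns={"activity_day_valid": "activity_valid"}),
            options.validity)
        week_nights = pd.DatetimeIndex(
            [pd.Timestamp(d) for d in grp["date"]])
        if len(night_index):
            in_week = kept_sleep[night_index.isin(week_nights)]
        else:
            in_week = kept_sleep
        slp_ok = validity.classify_sleep_week(in_week, options.validity)
        daily.loc[grp.index, "activity_week_valid"] = act_ok
        daily.loc[grp.index, "sleep_week_valid"] = slp_ok

    in_window = daily["segment"] != "out_of_window"
    daily["activity_valid"] = (daily["activity_day_valid"]
                               & daily["activity_week_valid"] & in_window)
    daily["sleep_valid"] = (daily["sleep_day_valid"]
                            & daily["sleep_week_valid"] & in_window)
    return ParticipantResult(profile=profile, daily=daily,
                             audited_sleep=audited, hr_grid=hr_grid, wear=wear)


def process_cohort(streams: list[RawParticipantStreams],
                   options: ProcessOptions | None = None) -> dict:
    """Process every participant and assemble cohort tables.

    Returns a dict with ``daily``, ``weekly``, ``period``, ``coverage``,
    ``coverage_summary`` and ``sleep_audit`` frames plus the per-participant
    results.
    """
    options = options or ProcessOptions()
    results = [process_participant(s.profile, s.steps, s.hr, s.sleep, options)
               for s in streams]
    if results:
        daily = pd.concat([r.daily for r in results], ignore_index=True)
        audit = pd.concat(
            [r.audited_sleep.assign(participant_id=r.profile.participant_id)
             for r in results], ignore_index=True)
    else:
        daily = pd.DataFrame(columns=["participant_id", "date", "segment",
                                      "activity_valid", "sleep_valid"])
        audit = pd.DataFrame(columns=["participant_id", "onset", "offset",
                                      "awake_minutes", "status", "reason"])
    timelines = {r.profile.participant_id: r.profile.timeline for r in results}
    in_window = daily[daily["segment"].isin(["pregnancy", "postpartum"])] \
        if len(daily) else daily
    coverage = validity.coverage_report(in_window, timelines) \
        if len(in_window) else pd.DataFrame(
            columns=["participant_id", "segment", "valid_activity_days",
                     "valid_sleep_days", "possible_days", "activity_pct",
                     "sleep_pct"])
    cov_summary = validity.coverage_summary(coverage) if len(coverage) \
        else pd.DataFrame()
    if len(daily):
        weekly, period = metrics.weekly_and_period_summaries(
            daily[daily["segment"] != "out_of_window"], options.validity)
    else:
        weekly, period = pd.DataFrame(), pd.DataFrame()
    return {
        "results": results, "daily": daily, "weekly": weekly,
        "period": period, "coverage": coverage,
        "coverage_summary": cov_summary, "sleep_audit": audit,
    }
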