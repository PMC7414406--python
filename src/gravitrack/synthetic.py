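"""Synthetic pregnancy-cohort generator emulating wrist-device raw streams.

Generates, for each simulated participant, the three raw streams a wrist
device exports — per-minute step counts, irregular heart-rate samples, and
device-scored sleep periods — over a monitoring window from gestational
week 13 to one month after delivery, together with a non-wear/sync-gap
missingness process.  The defaults encode the study conditions of a small
nulliparous cohort monitored continuously through pregnancy:

* 20 participants, age ~ N(26, 5) years;
* delivery at N(39.4, 2.6) gestational weeks;
* daily steps flat near 6838/day through gestational week 31, declining
  from week 32 toward a floor near the postpartum mean of 3705/day;
* nightly device-scored sleep near 477/457/393 minutes across the second
  trimester, third trimester and postpartum period, with nightly awake
  minutes near 21/32/67 built from awakening-count and duration draws;
* resting heart rate rising linearly from 60 bpm at week 13 to 70 bpm at
  week 32, plateauing until delivery and returning to baseline over the
  postpartum month;
* weekly moderate-to-vigorous activity with a cohort median near 46
  minutes, delivered as bin-aligned elevated-cadence/elevated-heart-rate
  bouts of 15 or 30 minutes;
* non-wear and whole-day sync gaps leaving roughly 60-75% of pregnancy
  days and 40-55% of postpartum days valid under the 10-awake-hour rule.

Heart-rate samples alternate between dense (~1.5 min spacing) and sparse
(~12 min spacing) regimes in 3-hour blocks so that downstream
homogenization exercises both its averaging and interpolation branches.
Every stream is reproducible bit-for-bit from the seed, with
per-participant derived substreams.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .timeline import GestationalTimeline, ParticipantProfile

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the simulated cohort (defaults = the emulated study)."""

    n_participants: int = 20
    age_mean: float = 26.0
    age_sd: float = 5.0
    delivery_mean_weeks: float = 39.4
    delivery_sd_weeks: float = 2.6

    # daily-step trajectory (steps/day): flat, then linear decline to floor
    step_period_means: tuple[float, float, float] = (6838.0, 5045.0, 3705.0)
    step_decline_start_week: int = 32
    step_decline_end_week: int = 36
    steps_between_sd: float = 1200.0
    steps_within_cv: float = 0.25        # lognormal day-to-day spread

    # nightly sleep (device-scored sleep minutes, excluding awake)
    sleep_period_means: tuple[float, float, float] = (477.0, 457.0, 393.0)
    sleep_between_sd: float = 25.0
    sleep_within_sd: float = 45.0
    awake_period_means: tuple[float, float, float] = (21.0, 32.0, 67.0)
    awake_minutes_per_event: float = 7.0

    # resting heart rate (bpm)
    resting_hr_start: float = 60.0
    resting_hr_peak: float = 70.0
    hr_peak_week: int = 32
    hr_between_sd: float = 4.0
    hr_noise_sd: float = 2.5

    # weekly MVPA bouts
    mvpa_weekly_median: float = 46.0
    mvpa_between_log_sd: float = 0.9
    mvpa_week_log_sd: float = 0.4
    mvpa_third_trimester_factor: float = 0.6
    mvpa_postpartum_factor: float = 0.35
    bout_cadence: float = 110.0

    # missingness: expected fraction of days invalidated per segment
    nonwear_rate_pregnancy: float = 0.28
    nonwear_rate_postpartum: float = 0.48
    short_nonwear_prob: float = 0.15     # benign 1-2 h gaps

    monitoring_start_week: int = 13
    monitoring_end_week: int = 42
    postpartum_days: int = 28
    base_date: dt.date = dt.date(2023, 1, 2)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name in ("age_sd", "delivery_sd_weeks", "steps_between_sd",
                     "steps_within_cv", "sleep_between_sd", "sleep_within_sd",
                     "hr_between_sd", "hr_noise_sd", "mvpa_between_log_sd",
                     "mvpa_week_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("nonwear_rate_pregnancy", "nonwear_rate_postpartum",
                     "short_nonwear_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(m < 0 for m in (*self.step_period_means,
                               *self.sleep_period_means,
                               *self.awake_period_means)):
            raise ValueError("means must be non-negative")


@dataclass
class RawParticipantStreams:
    """Device-like raw output of one simulated participant."""

    profile: ParticipantProfile
    steps: pd.Series             # minute timestamps -> int counts (sparse)
    hr: pd.Series                # sample timestamps -> bpm
    sleep: pd.DataFrame          # onset, offset, awake_minutes
    nonwear: list[tuple[pd.Timestamp, pd.Timestamp]]


# ---------------------------------------------------------------------------
# deterministic trajectories (shared with the noise-free oracle)


def expected_daily_steps(date: dt.date, timeline: GestationalTimeline,
                         config: CohortConfig) -> int:
    """Noise-free daily step total for a monitored date."""
    m2, _, m_pp = config.step_period_means
    if timeline.delivery_date is not None and date > timeline.delivery_date:
        return int(round(m_pp))
    week = timeline.gestational_week(date)
    w0, w1 = config.step_decline_start_week, config.step_decline_end_week
    if week < w0:
        return int(round(m2))
    if week >= w1:
        return int(round(m_pp))
    frac = (week - w0) / (w1 - w0)
    return int(round(m2 + frac * (m_pp - m2)))


def expected_resting_hr(date: dt.date, timeline: GestationalTimeline,
                        config: CohortConfig) -> float:
    """Noise-free resting heart-rate trajectory for a monitored date."""
    start_week = timeline.monitoring_start_week
    if timeline.delivery_date is not None and date > timeline.delivery_date:
        p = (date - timeline.delivery_date).days
        frac = min(p / max(config.postpartum_days, 1), 1.0)
        return config.resting_hr_peak + frac * (config.resting_hr_start
                                                - config.resting_hr_peak)
    week = timeline.gestational_week(date)
    if week >= config.hr_peak_week:
        return config.resting_hr_peak
    frac = (week - start_week) / (config.hr_peak_week - start_week)
    return config.resting_hr_start + frac * (config.resting_hr_peak
                                             - config.resting_hr_start)


def _period_index(date: dt.date, timeline: GestationalTimeline) -> int:
    """0 = second trimester, 1 = third, 2 = postpartum (calibration index)."""
    if timeline.delivery_date is not None and date > timeline.delivery_date:
        return 2
    return 0 if timeline.gestational_week(date) < 28 else 1


# ---------------------------------------------------------------------------
# sampling helpers


def sample_delivery_weeks(config: CohortConfig, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Gestational ages at delivery (weeks) drawn from the configured law."""
    return rng.normal(config.delivery_mean_weeks, config.delivery_sd_weeks,
                      size=n)


def _participant_rngs(seed: int, idx: int) -> list[np.random.Generator]:
    return [np.random.default_rng([seed & 0x7FFFFFFF, idx, j])
            for j in range(6)]


def _generate_participant(config: CohortConfig, idx: int) -> RawParticipantStreams:
    (rng_prof, rng_steps, rng_sleep,
     rng_hr, rng_nonwear, rng_mvpa) = _participant_rngs(config.rng_seed, idx)

    age = float(np.clip(rng_prof.normal(config.age_mean, config.age_sd),
                        18.0, 45.0))
    ga = float(np.clip(sample_delivery_weeks(config, 1, rng_prof)[0],
                       29.0, 43.0))
    conception = config.base_date + dt.timedelta(
        days=int(rng_prof.integers(0, 365)))
    delivery = conception + dt.timedelta(days=int(round(ga * 7)))
    profile = ParticipantProfile(
        participant_id=f"P{idx + 1:03d}", age=round(age, 1),
        conception_reference=conception, delivery_date=delivery,
        timeline_kwargs={
            "monitoring_start_week": config.monitoring_start_week,
            "monitoring_end_week": config.monitoring_end_week,
            "postpartum_days": config.postpartum_days,
        })
    timeline = profile.timeline
    dates = timeline.monitored_dates()
    nd = len(dates)
    start = pd.Timestamp(dates[0])

    period_idx = np.array([_period_index(d, timeline) for d in dates])
    gweeks = np.array([timeline.gestational_week(d) for d in dates])

    # --- per-day step totals -------------------------------------------------
    subj_step_off = rng_prof.normal(0.0, config.steps_between_sd)
    traj = np.array([expected_daily_steps(d, timeline, config) for d in dates],
                    dtype=float)
    day_mean = np.maximum(traj + subj_step_off, 500.0)
    cv = config.steps_within_cv
    factor = np.exp(rng_steps.normal(0.0, 1.0, nd) * cv - cv * cv / 2.0) \
        if cv > 0 else np.ones(nd)
    daily_total = np.round(day_mean * factor).astype(np.int64)

    # --- MVPA bout schedule (bin-aligned 15/30-minute units) -----------------
    propensity = config.mvpa_weekly_median * float(
        np.exp(rng_prof.normal(0.0, config.mvpa_between_log_sd)))
    period_factor = np.array([1.0, config.mvpa_third_trimester_factor,
                              config.mvpa_postpartum_factor])
    bout_len = np.zeros(nd, dtype=np.int64)      # minutes of bout per day
    bout_bin = np.zeros(nd, dtype=np.int64)      # starting 15-min bin index
    week_key = np.where(period_idx == 2, 1000 + (np.arange(nd) // 7), gweeks)
    for wk in np.unique(week_key):
        days_in_week = np.flatnonzero(week_key == wk)
        pf = period_factor[period_idx[days_in_week[0]]]
        weekly = propensity * pf * float(
            np.exp(rng_mvpa.normal(0.0, config.mvpa_week_log_sd)))
        n_units = int(min(round(weekly / 15.0), 2 * len(days_in_week)))
        if n_units <= 0:
            continue
        order = rng_mvpa.permutation(days_in_week)
        for u in range(n_units):
            d = order[u % len(order)]
            bout_len[d] = min(bout_len[d] + 15, 30)
        bout_bin[days_in_week] = 66 + rng_mvpa.integers(
            0, 8, len(days_in_week))             # between 16:30 and 18:30

    # --- minute-level step cadence ------------------------------------------
    n_min = nd * MINUTES_PER_DAY
    cadence = np.zeros(n_min, dtype=np.int64)
    bout_mask_minutes = np.zeros(n_min, dtype=bool)
    slots_per_day = np.arange(8 * 60, 21 * 60, 3)    # background comb 08:00-21:00
    cad_jitter = rng_steps.integers(-5, 6, nd)
    for d in range(nd):
        base = d * MINUTES_PER_DAY
        total = int(daily_total[d])
        if bout_len[d] > 0:
            cb = int(config.bout_cadence + cad_jitter[d])
            b0 = base + int(bout_bin[d]) * 15
            n_bout = int(bout_len[d])
            bout_steps = min(cb * n_bout, total)
            per = bout_steps // n_bout
            cadence[b0:b0 + n_bout] = per
            cadence[b0] += bout_steps - per * n_bout
            bout_mask_minutes[b0:b0 + n_bout] = True
            total -= bout_steps
        slots = base + slots_per_day
        per = total // len(slots)
        rem = total - per * len(slots)
        cadence[slots] += per
        cadence[slots[:rem]] += 1

    # --- sleep records -------------------------------------------------------
    subj_sleep_off = rng_prof.normal(0.0, config.sleep_between_sd)
    sleep_means = np.asarray(config.sleep_period_means)[period_idx]
    awake_means = np.asarray(config.awake_period_means)[period_idx]
    onset_min = (23 * 60 + np.round(rng_sleep.normal(0, 30, nd))).astype(int)
    sleep_min = np.maximum(np.round(
        rng_sleep.normal(sleep_means + subj_sleep_off,
                         config.sleep_within_sd)), 240).astype(int)
    lam = awake_means / config.awake_minutes_per_event
    n_events = rng_sleep.poisson(lam)
    awake_min = np.zeros(nd, dtype=int)
    for d in range(nd):
        if n_events[d] > 0:
            durs = np.maximum(np.round(rng_sleep.exponential(
                config.awake_minutes_per_event, n_events[d])), 1)
            awake_min[d] = int(durs.sum())
    sleep_rows = []
    for d in range(nd):
        onset = start + pd.Timedelta(minutes=d * MINUTES_PER_DAY + onset_min[d])
        offset = onset + pd.Timedelta(minutes=int(sleep_min[d] + awake_min[d]))
        sleep_rows.append((onset, offset, float(awake_min[d])))
    sleep_mask_minutes = np.zeros(n_min + 2 * MINUTES_PER_DAY, dtype=bool)
    for d in range(nd):
        i0 = d * MINUTES_PER_DAY + onset_min[d]
        sleep_mask_minutes[i0:i0 + sleep_min[d] + awake_min[d]] = True
    sleep_mask_minutes = sleep_mask_minutes[:n_min]

    # --- non-wear / sync-gap process ----------------------------------------
    rate = np.where(period_idx == 2, config.nonwear_rate_postpartum,
                    config.nonwear_rate_pregnancy)
    p_gap = 0.45 * rate
    p_long = np.divide(0.55 * rate, 1.0 - p_gap,
                       out=np.zeros_like(rate), where=(1.0 - p_gap) > 0)
    u = rng_nonwear.uniform(size=nd)
    is_gap = u < p_gap
    is_long = ~is_gap & (rng_nonwear.uniform(size=nd) < p_long)
    is_short = ~is_gap & ~is_long & (
        rng_nonwear.uniform(size=nd) < config.short_nonwear_prob)
    nonwear_mask = np.zeros(n_min, dtype=bool)
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for d in range(nd):
        base = d * MINUTES_PER_DAY
        if is_gap[d]:
            i0, i1 = base, base + MINUTES_PER_DAY
        elif is_long[d]:
            s = int(rng_nonwear.integers(8 * 60, 12 * 60))
            dur = int(rng_nonwear.integers(7 * 60, 13 * 60))
            i0, i1 = base + s, min(base + s + dur, n_min)
        elif is_short[d]:
            s = int(rng_nonwear.integers(9 * 60, 19 * 60))
            dur = int(rng_nonwear.integers(60, 121))
            i0, i1 = base + s, min(base + s + dur, n_min)
        else:
            continue
        nonwear_mask[i0:i1] = True
        intervals.append((start + pd.Timedelta(minutes=i0),
                          start + pd.Timedelta(minutes=i1)))
    cadence[nonwear_mask] = 0

    # --- heart-rate samples --------------------------------------------------
    subj_hr_off = rng_prof.normal(0.0, config.hr_between_sd)
    r_day = np.array([expected_resting_hr(d, timeline, config) for d in dates]) \
        + subj_hr_off
    blocks_per_day = 8
    n_blocks = nd * blocks_per_day
    dense = rng_hr.uniform(size=n_blocks) < 0.5
    spacing = np.where(dense, rng_hr.uniform(70, 130, n_blocks),
                       rng_hr.uniform(600, 900, n_blocks))
    # night blocks (21:00-09:00) sample steadily: optical sleep tracking
    # keeps the sensor duty cycle high, and a max gap of 7 min guarantees
    # every 15-minute bin over a worn sleep period is directly averaged
    block_of_day = np.arange(n_blocks) % blocks_per_day
    night_block = np.isin(block_of_day, (7, 0, 1, 2))
    spacing = np.where(night_block & ~dense,
                       rng_hr.uniform(150, 420, n_blocks), spacing)
    block_seconds = 3 * 3600
    n_per_block = (block_seconds / spacing).astype(np.int64)
    block_starts = np.arange(n_blocks, dtype=np.int64) * block_seconds
    sample_block = np.repeat(np.arange(n_blocks), n_per_block)
    within = np.concatenate([np.arange(c) for c in n_per_block]) \
        if n_per_block.sum() else np.empty(0, dtype=np.int64)
    t_sec = (block_starts[sample_block]
             + ((within + 0.5) * spacing[sample_block])).astype(np.int64)
    t_sec = np.unique(t_sec)
    minute_idx = t_sec // 60
    keep = ~nonwear_mask[np.minimum(minute_idx, n_min - 1)] & (minute_idx < n_min)
    t_sec, minute_idx = t_sec[keep], minute_idx[keep]

    day_idx = minute_idx // MINUTES_PER_DAY
    hour = (minute_idx % MINUTES_PER_DAY) / 60.0
    asleep = sleep_mask_minutes[minute_idx]
    base_hr = r_day[day_idx]
    bump = 8.0 * np.clip(np.sin(np.pi * (hour - 6.5) / 16.0), 0.0, 1.0)
    bump[asleep] = 0.0
    noise = rng_hr.normal(0.0, config.hr_noise_sd, len(t_sec))
    values = base_hr + bump + np.where(asleep, np.abs(noise), noise)
    in_bout = bout_mask_minutes[minute_idx]
    max_hr = 220.0 - age
    values[in_bout] = (base_hr[in_bout]
                       + 0.5 * (max_hr - base_hr[in_bout])
                       + noise[in_bout])
    values = np.clip(values, 30.0, 220.0)

    hr = pd.Series(np.round(values, 1),
                   index=start + pd.to_timedelta(t_sec, unit="s"), name="bpm")

    nz = np.flatnonzero(cadence)
    steps = pd.Series(cadence[nz],
                      index=start + pd.to_timedelta(nz, unit="m"), name="steps")

    sleep = pd.DataFrame(sleep_rows, columns=["onset", "offset", "awake_minutes"])
    drop_gap = np.array([is_gap[d] for d in range(nd)])
    sleep = sleep[~drop_gap].reset_index(drop=True)
    # the final night spills past the monitoring span and goes unrecorded
    end_ts = start + pd.Timedelta(minutes=n_min)
    sleep = sleep[sleep["offset"] <= end_ts].reset_index(drop=True)

    return RawParticipantStreams(profile=profile, steps=steps, hr=hr,
                                 sleep=sleep, nonwear=intervals)


def sample_cohort(config: CohortConfig) -> list[RawParticipantStreams]:
    """Generate the full cohort of raw participant streams.

    Deterministic: identical config (including seed) yields bit-identical
    streams; participants use derived substreams, so participant ``i`` is
    unchanged by the presence of other participants.
    """
    return [_generate_participant(config, i)
            for i in range(config.n_participants)]


def write_cohort(streams: list[RawParticipantStreams],
                 destination: str | Path) -> Path:
    """Write per-participant stream files plus a manifest; returns manifest path.

    Output uses the documented flat-CSV formats and round-trips losslessly
    through the ingestion readers.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in streams:
        pid = s.profile.participant_id
        steps_file = f"{pid}_steps.csv"
        hr_file = f"{pid}_hr.csv"
        sleep_file = f"{pid}_sleep.csv"
        gio.write_step_stream(s.steps, pid, dest / steps_file)
        gio.write_hr_stream(s.hr, pid, dest / hr_file)
        gio.write_sleep_records(s.sleep, pid, dest / sleep_file)
        entries.append(gio.ManifestEntry(profile=s.profile,
                                         steps_file=steps_file,
                                         hr_file=hr_file,
                                         sleep_file=sleep_file))
    manifest_path = dest / "manifest.csv"
    gio.write_manifest(entries, manifest_path)
    return manifest_path
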