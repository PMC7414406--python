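"""Device-stream preprocessing: heart-rate homogenization, wear detection,
and automated cross-checking of device-scored sleep.

Wrist devices report heart rate at irregular rates.  The pipeline first
*homogenizes* the samples onto a regular 15-minute grid (averaging samples
within a bin, then linearly interpolating short gaps between averaged
bins), derives a per-minute wear mask from heart-rate contact and step
movement, and finally validates each device-scored sleep period against
the wear mask and step activity, removing or trimming mismatched periods
with an audit reason.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

PROV_AVERAGED = "averaged"
PROV_INTERPOLATED = "interpolated"
PROV_MISSING = "missing"

#: sleep audit statuses
STATUS_ACCEPTED = "accepted"
STATUS_TRIMMED = "trimmed"
STATUS_REMOVED = "removed"


def _day_span(index: pd.DatetimeIndex,
              span: tuple[pd.Timestamp, pd.Timestamp] | None,
              ) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Midnight-anchored [start, end) covering ``index`` or the given span."""
    if span is not None:
        start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    elif len(index):
        start = index[0].normalize()
        end = index[-1].normalize() + pd.Timedelta(days=1)
    else:
        raise ValueError("cannot infer a time span from an empty series")
    if start != start.normalize() or end != end.normalize():
        raise ValueError("span bounds must be local midnights")
    return start, end


def homogenize_heart_rate(
    samples: pd.Series,
    bin_width: pd.Timedelta = pd.Timedelta(minutes=15),
    max_gap: pd.Timedelta = pd.Timedelta(minutes=60),
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> pd.DataFrame:
    """Homogenize irregular heart-rate samples onto a regular bin grid.

    Bins containing at least one sample receive the arithmetic mean of the
    contained samples (provenance ``averaged``).  Runs of empty bins lying
    between two averaged bins no farther apart than ``max_gap`` are filled
    by linear interpolation between the two averaged bin values (provenance
    ``interpolated``).  All other bins are ``missing``.

    The grid is anchored to local midnight and spans whole days, so the
    output always has exactly ``span / bin_width`` bins regardless of input
    sparsity.

    Returns a frame indexed by bin start with columns ``value`` (bpm,
    NaN when missing) and ``provenance``.
    """
    if not samples.index.is_monotonic_increasing or samples.index.has_duplicates:
        raise ValueError("heart-rate samples must be sorted with unique timestamps")
    if (pd.Timedelta(days=1) % bin_width) != pd.Timedelta(0):
        raise ValueError("bin_width must divide 24 h evenly")
    start, end = _day_span(samples.index, span)
    grid = pd.date_range(start, end, freq=bin_width, inclusive="left")

    values = np.full(len(grid), np.nan)
    if len(samples):
        inside = (samples.index >= start) & (samples.index < end)
        s = samples[inside]
        if len(s):
            bin_idx = ((s.index - start) // bin_width).astype(np.int64)
            sums = np.bincount(bin_idx, weights=s.to_numpy(), minlength=len(grid))
            counts = np.bincount(bin_idx, minlength=len(grid))
            with np.errstate(invalid="ignore"):
                values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    provenance = np.where(np.isfinite(values), PROV_AVERAGED,
                          PROV_MISSING).astype(object)

    # linear interpolation of short gaps between averaged bins
    max_gap_bins = int(max_gap // bin_width)
    averaged_pos = np.flatnonzero(provenance == PROV_AVERAGED)
    for left, right in zip(averaged_pos[:-1], averaged_pos[1:]):
        gap = right - left
        if 1 < gap <= max_gap_bins:
            frac = np.arange(1, gap) / gap
            values[left + 1:right] = values[left] + frac * (values[right] - values[left])
            provenance[left + 1:right] = PROV_INTERPOLATED

    return pd.DataFrame({"value": values, "provenance": provenance}, index=grid)


def minute_grid(start: pd.Timestamp, end: pd.Timestamp) -> pd.DatetimeIndex:
    return pd.date_range(start, end, freq="min", inclusive="left")


def steps_on_grid(steps: pd.Series, start: pd.Timestamp,
                  end: pd.Timestamp) -> pd.Series:
    """Project a sparse minute step series onto a dense grid, absent = 0."""
    grid = minute_grid(start, end)
    return steps.reindex(grid, fill_value=0).astype(np.int64)


def detect_wear(
    hr_grid: pd.DataFrame,
    steps: pd.Series,
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> pd.Series:
    """Per-minute wear mask from heart-rate contact and step movement.

    A minute is worn iff its covering heart-rate bin was directly averaged
    from samples (interpolated bins are not wear evidence), or the minute
    itself recorded a positive step count.  Empty inputs yield all
    not-worn.
    """
    if span is not None:
        start, end = _day_span(pd.DatetimeIndex([]), span)
    else:
        start, end = hr_grid.index[0], hr_grid.index[-1] + (
            hr_grid.index[1] - hr_grid.index[0] if len(hr_grid) > 1
            else pd.Timedelta(minutes=15))
    grid = minute_grid(start, end)
    worn = np.zeros(len(grid), dtype=bool)

    if len(hr_grid):
        bin_width = (hr_grid.index[1] - hr_grid.index[0]) if len(hr_grid) > 1 \
            else pd.Timedelta(minutes=15)
        per_bin = (hr_grid["provenance"] == PROV_AVERAGED).to_numpy()
        mins_per_bin = int(bin_width // pd.Timedelta(minutes=1))
        hr_minutes = np.repeat(per_bin, mins_per_bin)
        hr_index = minute_grid(hr_grid.index[0],
                               hr_grid.index[-1] + bin_width)
        hr_mask = pd.Series(hr_minutes, index=hr_index)
        worn |= hr_mask.reindex(grid, fill_value=False).to_numpy()

    if len(steps):
        step_mask = steps_on_grid(steps, start, end).to_numpy() > 0
        worn |= step_mask
    return pd.Series(worn, index=grid, name="worn")


REASON_OFF_WRIST = "off-wrist"
REASON_MOVEMENT = "movement-mismatch"
REASON_ALL_MOVEMENT = "all-movement"
REASON_BOUNDARY = "boundary-movement"


def cross_check_sleep(
    sleep: pd.DataFrame,
    steps: pd.Series,
    wear: pd.Series,
    movement_fraction_threshold: float = 0.10,
) -> pd.DataFrame:
    """Validate device-scored sleep periods against wear and movement.

    Automated counterpart of a manual cross-check of sleep against hand
    movement and heart-rate contact:

    * any not-worn minute inside the period -> ``removed`` (off-wrist);
    * fraction of minutes with positive steps above
      ``movement_fraction_threshold`` -> ``removed`` (movement-mismatch);
    * leading/trailing runs of positive-step minutes -> ``trimmed`` to the
      interior, with device awake minutes rescaled proportionally to the
      retained duration;
    * otherwise ``accepted`` unchanged.

    Returns a frame with columns ``onset``, ``offset``, ``awake_minutes``,
    ``status``, ``reason`` (one audit row per input period).  The operation
    is idempotent on its own accepted/trimmed output.
    """
    out_rows = []
    wear_arr = wear.to_numpy()
    wear_start = wear.index[0] if len(wear) else None
    steps_dense = steps if steps.index.is_monotonic_increasing else steps.sort_index()

    for _, row in sleep.iterrows():
        onset = pd.Timestamp(row["onset"]).floor("min")
        offset = pd.Timestamp(row["offset"]).ceil("min")
        awake = float(row["awake_minutes"])
        n_min = int((offset - onset) // pd.Timedelta(minutes=1))

        if wear_start is None:
            worn_mins = np.zeros(n_min, dtype=bool)
        else:
            i0 = int((onset - wear_start) // pd.Timedelta(minutes=1))
            idx = np.arange(i0, i0 + n_min)
            inside = (idx >= 0) & (idx < len(wear_arr))
            worn_mins = np.zeros(n_min, dtype=bool)
            worn_mins[inside] = wear_arr[idx[inside]]

        grid = pd.date_range(onset, offset, freq="min", inclusive="left")
        step_mins = steps_dense.reindex(grid, fill_value=0).to_numpy() > 0

        def emit(status: str, reason: str, new_onset=onset, new_offset=offset,
                 new_awake=awake) -> None:
            out_rows.append({
                "onset": new_onset, "offset": new_offset,
                "awake_minutes": new_awake, "status": status, "reason": reason,
            })

        if not worn_mins.all():
            emit(STATUS_REMOVED, REASON_OFF_WRIST)
            continue
        if n_min > 0 and step_mins.mean() > movement_fraction_threshold:
            emit(STATUS_REMOVED, REASON_MOVEMENT)
            continue

        lead = int(np.argmax(~step_mins)) if not step_mins.all() else n_min
        trail = int(np.argmax(~step_mins[::-1])) if not step_mins.all() else 0
        if lead == n_min:
            emit(STATUS_REMOVED, REASON_ALL_MOVEMENT)
            continue
        if lead or trail:
            new_onset = onset + pd.Timedelta(minutes=lead)
            new_offset = offset - pd.Timedelta(minutes=trail)
            kept = n_min - lead - trail
            new_awake = awake * kept / n_min if n_min else awake
            emit(STATUS_TRIMMED, REASON_BOUNDARY, new_onset, new_offset, new_awake)
            continue
        emit(STATUS_ACCEPTED, "")

    return pd.DataFrame(
        out_rows,
        columns=["onset", "offset", "awake_minutes", "status", "reason"],
    )


def onset_night(onsets) -> pd.DatetimeIndex:
    """Night label of sleep onsets: noon-to-noon calendar attribution.

    The night of calendar day ``d`` covers onsets from 12:00 on ``d`` to
    12:00 the next day, so a post-midnight return to sleep stays with the
    night it interrupted.
    """
    return (pd.DatetimeIndex(onsets) - pd.Timedelta(hours=12)).normalize()


def retained_sleep(audited: pd.DataFrame) -> pd.DataFrame:
    """Accepted and trimmed periods of an audited sleep set."""
    keep = audited["status"].isin([STATUS_ACCEPTED, STATUS_TRIMMED])
    return audited[keep].reset_index(drop=True)


def sleep_minute_mask(audited: pd.DataFrame, start: pd.Timestamp,
                      end: pd.Timestamp) -> np.ndarray:
    """Boolean per-minute mask of retained sleep over [start, end)."""
    grid_len = int((end - start) // pd.Timedelta(minutes=1))
    mask = np.zeros(grid_len, dtype=bool)
    for _, row in retained_sleep(audited).iterrows():
        onset = pd.Timestamp(row["onset"]).floor("min")
        offset = pd.Timestamp(row["offset"]).ceil("min")
        i0 = max(0, int((onset - start) // pd.Timedelta(minutes=1)))
        i1 = min(grid_len, int((offset - start) // pd.Timedelta(minutes=1)))
        if i1 > i0:
            mask[i0:i1] = True
    return mask
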