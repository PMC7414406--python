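"""Readers and writers for raw stream files and the participant manifest.

All on-disk formats are flat UTF-8 CSV with a header row and ISO-8601
timestamps, one file per participant per stream:

``steps``    ``participant_id,timestamp,steps`` — whole-minute timestamps,
             non-negative integer counts, gaps permitted.
``hr``       ``participant_id,timestamp,bpm`` — arbitrary (irregular)
             second-resolution timestamps, bpm in [30, 220].
``sleep``    ``participant_id,onset,offset,awake_minutes`` — device-scored
             sleep periods, non-overlapping, awake minutes <= duration.
``manifest`` ``participant_id,age,conception_reference,delivery_date,
             pregnancy_only,steps_file,hr_file,sleep_file``.

Structurally malformed rows (unparseable timestamps or numbers, wrong field
counts) are collected into a rejects report — never silently dropped — while
invariant violations (duplicate or non-increasing timestamps, negative
counts, out-of-range bpm, overlapping sleep periods) abort the read with a
:class:`FormatError` naming the offending line.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .timeline import ParticipantProfile, TimelineError

HR_MIN_BPM = 30.0
HR_MAX_BPM = 220.0


class FormatError(ValueError):
    """A stream file violates its documented schema or invariants."""


@dataclass
class RejectedRow:
    source: str
    line: int          # 1-based physical line number (header = line 1)
    reason: str        # short reason code
    content: str


def rejects_frame(rejects: list[RejectedRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.source, r.line, r.reason, r.content) for r in rejects],
        columns=["source", "line", "reason", "content"],
    )


def write_rejects_report(rejects: list[RejectedRow], path: str | Path) -> None:
    rejects_frame(rejects).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# shared parsing helpers


def _read_raw(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != columns:
        raise FormatError(
            f"{path}: header {list(raw.columns)} does not match schema {columns}"
        )
    return raw

def _collect(raw: pd.DataFrame, bad: pd.Series, source: str, reason: str,
             rejects: list[RejectedRow] | None) -> pd.DataFrame:
    """Move rows flagged in ``bad`` to the rejects list; return the rest."""
    if bad.any():
        if rejects is not None:
            for idx in raw.index[bad]:
                content = ",".join(raw.loc[idx].astype(str))
                rejects.append(RejectedRow(source, int(idx) + 2, reason, content))
        raw = raw[~bad]
    return raw


def _parse_times(raw: pd.DataFrame, col: str, source: str,
                 rejects: list[RejectedRow] | None) -> tuple[pd.DataFrame, pd.Series]:
    ts = pd.to_datetime(raw[col], errors="coerce", format="ISO8601")
    raw = _collect(raw, ts.isna() & (raw[col] != ""), source, f"bad-{col}", rejects)
    raw = _collect(raw, raw[col] == "", source, f"missing-{col}", rejects)
    return raw, pd.to_datetime(raw[col], format="ISO8601")


def _check_increasing(ts: pd.Series, path: Path) -> None:
    if len(ts) < 2:
        return
    diffs = ts.to_numpy()[1:] <= ts.to_numpy()[:-1]
    if diffs.any():
        i = int(np.argmax(diffs))
        line = int(ts.index[i + 1]) + 2
        if ts.iloc[i + 1] == ts.iloc[i]:
            raise FormatError(
                f"{path}: duplicate timestamp {ts.iloc[i + 1]} at line {line}"
            )
        raise FormatError(
            f"{path}: timestamps not strictly increasing at line {line}"
        )


# ---------------------------------------------------------------------------
# step stream


def read_step_stream(path: str | Path,
                     rejects: list[RejectedRow] | None = None) -> pd.Series:
    """Read a per-minute step file into an int series indexed by timestamp.

    Timestamps must be strictly increasing and minute-aligned; counts are
    non-negative integers.  Gaps (absent minutes) are permitted and mean
    "no steps recorded".
    """
    path = Path(path)
    raw = _read_raw(path, ["participant_id", "timestamp", "steps"])
    raw, ts = _parse_times(raw, "timestamp", path.name, rejects)
    counts = pd.to_numeric(raw["steps"], errors="coerce")
    raw = _collect(raw, counts.isna(), path.name, "bad-steps", rejects)
    ts = ts[raw.index]
    counts = counts[raw.index]
    bad_neg = counts < 0
    if bad_neg.any():
        line = int(raw.index[bad_neg.to_numpy()][0]) + 2
        raise FormatError(f"{path}: negative step count at line {line}")
    misaligned = (ts.dt.second != 0) | (ts.dt.microsecond != 0)
    raw = _collect(raw, misaligned, path.name, "sub-minute-timestamp", rejects)
    ts, counts = ts[raw.index], counts[raw.index]
    _check_increasing(ts, path)
    out = pd.Series(counts.to_numpy(dtype=np.int64),
                    index=pd.DatetimeIndex(ts.to_numpy()), name="steps")
    return out


def write_step_stream(steps: pd.Series, participant_id: str,
                      path: str | Path) -> None:
    df = pd.DataFrame({
        "participant_id": participant_id,
        "timestamp": steps.index.strftime("%Y-%m-%dT%H:%M:%S"),
        "steps": steps.to_numpy(dtype=np.int64),
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# heart-rate stream


def read_hr_stream(path: str | Path,
                   rejects: list[RejectedRow] | None = None) -> pd.Series:
    """Read an irregular heart-rate sample file into a float bpm series."""
    path = Path(path)
    raw = _read_raw(path, ["participant_id", "timestamp", "bpm"])
    raw, ts = _parse_times(raw, "timestamp", path.name, rejects)
    bpm = pd.to_numeric(raw["bpm"], errors="coerce")
    raw = _collect(raw, bpm.isna(), path.name, "bad-bpm", rejects)
    ts, bpm = ts[raw.index], bpm[raw.index]
    out_of_range = (bpm < HR_MIN_BPM) | (bpm > HR_MAX_BPM)
    if out_of_range.any():
        line = int(raw.index[out_of_range.to_numpy()][0]) + 2
        raise FormatError(
            f"{path}: bpm outside [{HR_MIN_BPM:g}, {HR_MAX_BPM:g}] at line {line}"
        )
    _check_increasing(ts, path)
    return pd.Series(bpm.to_numpy(dtype=float),
                     index=pd.DatetimeIndex(ts.to_numpy()), name="bpm")


def write_hr_stream(hr: pd.Series, participant_id: str, path: str | Path) -> None:
    df = pd.DataFrame({
        "participant_id": participant_id,
        "timestamp": hr.index.strftime("%Y-%m-%dT%H:%M:%S"),
        "bpm": np.round(hr.to_numpy(dtype=float), 1),
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sleep records


def read_sleep_records(path: str | Path,
                       rejects: list[RejectedRow] | None = None) -> pd.DataFrame:
    """Read device-scored sleep periods.

    Returns a frame with columns ``onset``, ``offset``, ``awake_minutes``
    sorted by onset.  Overlapping periods, non-positive durations and awake
    minutes exceeding the period duration are format errors.
    """
    path = Path(path)
    raw = _read_raw(path, ["participant_id", "onset", "offset", "awake_minutes"])
    raw, onset = _parse_times(raw, "onset", path.name, rejects)
    raw, offset = _parse_times(raw, "offset", path.name, rejects)
    onset = onset[raw.index]
    awake = pd.to_numeric(raw["awake_minutes"], errors="coerce")
    raw = _collect(raw, awake.isna(), path.name, "bad-awake-minutes", rejects)
    onset, offset, awake = onset[raw.index], offset[raw.index], awake[raw.index]

    df = pd.DataFrame({
        "onset": onset.to_numpy(),
        "offset": offset.to_numpy(),
        "awake_minutes": awake.to_numpy(dtype=float),
    }, index=raw.index)
    bad_dur = df["offset"] <= df["onset"]
    if bad_dur.any():
        line = int(df.index[bad_dur.to_numpy()][0]) + 2
        raise FormatError(f"{path}: offset not after onset at line {line}")
    duration = (df["offset"] - df["onset"]).dt.total_seconds() / 60.0
    bad_awake = (df["awake_minutes"] < 0) | (df["awake_minutes"] > duration)
    if bad_awake.any():
        line = int(df.index[bad_awake.to_numpy()][0]) + 2
        raise FormatError(
            f"{path}: awake minutes outside [0, duration] at line {line}"
        )
    df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    overlap = df["onset"].to_numpy()[1:] < df["offset"].to_numpy()[:-1]
    if overlap.any():
        raise FormatError(f"{path}: overlapping sleep periods")
    return df


def write_sleep_records(sleep: pd.DataFrame, participant_id: str,
                        path: str | Path) -> None:
    df = pd.DataFrame({
        "participant_id": participant_id,
        "onset": pd.DatetimeIndex(sleep["onset"]).strftime("%Y-%m-%dT%H:%M:%S"),
        "offset": pd.DatetimeIndex(sleep["offset"]).strftime("%Y-%m-%dT%H:%M:%S"),
        "awake_minutes": sleep["awake_minutes"].to_numpy(dtype=float),
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# manifest


MANIFEST_COLUMNS = [
    "participant_id", "age", "conception_reference", "delivery_date",
    "pregnancy_only", "steps_file", "hr_file", "sleep_file",
]


@dataclass
class ManifestEntry:
    profile: ParticipantProfile
    steps_file: str
    hr_file: str
    sleep_file: str


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read the participant manifest into profiles plus stream file names.

    A missing delivery date is only accepted for rows flagged
    ``pregnancy_only``; any unparseable date or timeline-invariant violation
    is a format error naming the row.
    """
    path = Path(path)
    raw = _read_raw(path, MANIFEST_COLUMNS)
    entries: list[ManifestEntry] = []
    for idx, row in raw.iterrows():
        line = int(idx) + 2
        try:
            conception = dt.date.fromisoformat(row["conception_reference"])
        except ValueError as exc:
            raise FormatError(
                f"{path}: bad conception_reference at line {line}: {exc}"
            ) from None
        pregnancy_only = row["pregnancy_only"].strip().lower() in ("1", "true", "yes")
        delivery: dt.date | None = None
        if row["delivery_date"].strip():
            try:
                delivery = dt.date.fromisoformat(row["delivery_date"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: bad delivery_date at line {line}: {exc}"
                ) from None
        try:
            age = float(row["age"])
        except ValueError:
            raise FormatError(f"{path}: bad age at line {line}") from None
        try:
            profile = ParticipantProfile(
                participant_id=row["participant_id"],
                age=age,
                conception_reference=conception,
                delivery_date=delivery,
                pregnancy_only=pregnancy_only,
            )
            profile.timeline  # force timeline invariant checks
        except TimelineError as exc:
            raise FormatError(f"{path}: line {line}: {exc}") from None
        entries.append(ManifestEntry(
            profile=profile,
            steps_file=row["steps_file"],
            hr_file=row["hr_file"],
            sleep_file=row["sleep_file"],
        ))
    return entries


def write_manifest(entries: list[ManifestEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        p = e.profile
        rows.append({
            "participant_id": p.participant_id,
            "age": p.age,
            "conception_reference": p.conception_reference.isoformat(),
            "delivery_date": "" if p.delivery_date is None
                             else p.delivery_date.isoformat(),
            "pregnancy_only": str(p.pregnancy_only).lower(),
            "steps_file": e.steps_file,
            "hr_file": e.hr_file,
            "sleep_file": e.sleep_file,
        })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
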