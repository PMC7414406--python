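"""Gestational and postpartum calendar arithmetic.

Every stage of the pipeline locates calendar dates on a gestational
timeline anchored at gestational day 0 (the start of week 1, i.e. the
last-menstrual-period reference).  The week convention is the obstetric
one: gestational week ``w`` covers gestational days ``7*(w-1)`` through
``7*w - 1`` inclusive, so "week 13 to 42" spans exactly
``7 * (42 - 13) = 203`` days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum


class Period(str, Enum):
    """Analysis period labels over the monitoring window."""

    SECOND_TRIMESTER = "second_trimester"
    THIRD_TRIMESTER = "third_trimester"
    POSTPARTUM = "postpartum"
    OUT_OF_WINDOW = "out_of_window"


#: First gestational week of the third trimester (completed-weeks split 27/28).
THIRD_TRIMESTER_START_WEEK = 28


class TimelineError(ValueError):
    """Raised for dates or parameters outside the timeline's domain."""


@dataclass(frozen=True)
class GestationalTimeline:
    """Calendar coordinate system of one pregnancy.

    Parameters
    ----------
    conception_reference
        Calendar date of gestational day 0 (start of gestational week 1).
    delivery_date
        Calendar date of delivery; ``None`` for pregnancy-only participants.
    monitoring_start_week, monitoring_end_week
        Gestational weeks bounding the pregnancy monitoring window.  The
        window is half-open: it covers the start of ``monitoring_start_week``
        up to (excluding) the start of ``monitoring_end_week``.
    postpartum_days
        Length of the postpartum monitoring segment, in days strictly after
        the delivery date (the delivery day itself belongs to pregnancy).
    """

    conception_reference: dt.date
    delivery_date: dt.date | None = None
    monitoring_start_week: int = 13
    monitoring_end_week: int = 42
    postpartum_days: int = 28

    def __post_init__(self) -> None:
        if self.monitoring_end_week <= self.monitoring_start_week:
            raise TimelineError(
                "monitoring_end_week must exceed monitoring_start_week "
                f"(got {self.monitoring_start_week}..{self.monitoring_end_week})"
            )
        if self.postpartum_days < 0:
            raise TimelineError("postpartum_days must be non-negative")
        if self.delivery_date is not None:
            if self.delivery_date < self.monitoring_start_date:
                raise TimelineError(
                    f"delivery {self.delivery_date} precedes the start of "
                    f"monitoring week {self.monitoring_start_week}"
                )

    # -- anchor dates ------------------------------------------------------

    @property
    def monitoring_start_date(self) -> dt.date:
        """First day of gestational week ``monitoring_start_week``."""
        return self.week_start(self.monitoring_start_week)

    @property
    def pregnancy_end_date(self) -> dt.date:
        """Last pregnancy-segment day: delivery date, capped at the window end."""
        window_last = self.week_start(self.monitoring_end_week) - dt.timedelta(days=1)
        if self.delivery_date is None:
            return window_last
        return min(self.delivery_date, window_last)

    @property
    def monitoring_end_date(self) -> dt.date:
        """Last monitored day (end of postpartum, or of pregnancy window)."""
        if self.delivery_date is None:
            return self.pregnancy_end_date
        return self.delivery_date + dt.timedelta(days=self.postpartum_days)

    def week_start(self, week: int) -> dt.date:
        """Calendar date of the first day of gestational week ``week``."""
        return self.conception_reference + dt.timedelta(days=7 * (week - 1))

    # -- coordinate maps ---------------------------------------------------

    def gestational_day(self, date: dt.date) -> int:
        d = (date - self.conception_reference).days
        if d < 0:
            raise TimelineError(f"{date} precedes conception reference")
        return d

    def gestational_week(self, date: dt.date) -> int:
        """Gestational week of ``date`` (week 1 = gestational days 0-6)."""
        return self.gestational_day(date) // 7 + 1

    def postpartum_day(self, date: dt.date) -> int | None:
        """1-based day-after-delivery index, or None before/at delivery."""
        if self.delivery_date is None:
            return None
        d = (date - self.delivery_date).days
        return d if d >= 1 else None

    def assign_period(self, date: dt.date) -> Period:
        """Partition the monitoring window into trimester/postpartum labels.

        Second trimester = weeks ``monitoring_start_week``..27, third
        trimester = week 28 through the delivery date, postpartum = the
        ``postpartum_days`` days strictly after delivery.  Dates outside the
        monitoring window get the explicit out-of-window sentinel.
        """
        if date < self.monitoring_start_date or date > self.monitoring_end_date:
            return Period.OUT_OF_WINDOW
        if self.delivery_date is not None and date > self.delivery_date:
            pp = (date - self.delivery_date).days
            if pp <= self.postpartum_days:
                return Period.POSTPARTUM
            return Period.OUT_OF_WINDOW
        if date > self.pregnancy_end_date:
            return Period.OUT_OF_WINDOW
        if self.gestational_week(date) < THIRD_TRIMESTER_START_WEEK:
            return Period.SECOND_TRIMESTER
        return Period.THIRD_TRIMESTER

    def is_delivery_week(self, date: dt.date) -> bool:
        """True for pregnancy days of the gestational week containing delivery.

        The delivery week is truncated (it ends at delivery), which is why
        the validity rules relax there; days after delivery belong to the
        postpartum segment and are not part of the delivery week.
        """
        if self.delivery_date is None or date > self.delivery_date:
            return False
        return self.gestational_week(date) == self.gestational_week(self.delivery_date)

    def possible_monitoring_days(self, segment: str) -> int:
        """Fixed possible-day denominator for a monitoring segment.

        The pregnancy denominator is the full half-open window
        ``7 * (monitoring_end_week - monitoring_start_week)`` days,
        independent of the actual delivery date; the postpartum denominator
        is ``postpartum_days``.
        """
        if segment == "pregnancy":
            return 7 * (self.monitoring_end_week - self.monitoring_start_week)
        if segment == "postpartum":
            return self.postpartum_days
        raise TimelineError(f"unknown segment {segment!r}")

    def monitored_dates(self) -> list[dt.date]:
        """All calendar dates of the monitoring window, in order."""
        n = (self.monitoring_end_date - self.monitoring_start_date).days + 1
        return [self.monitoring_start_date + dt.timedelta(days=i) for i in range(n)]


@dataclass(frozen=True)
class ParticipantProfile:
    """Identity and pregnancy anchors of one cohort member."""

    participant_id: str
    age: float
    conception_reference: dt.date
    delivery_date: dt.date | None = None
    pregnancy_only: bool = False
    timeline_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delivery_date is None and not self.pregnancy_only:
            raise TimelineError(
                f"participant {self.participant_id}: missing delivery date "
                "is only allowed for pregnancy-only participants"
            )

    @property
    def timeline(self) -> GestationalTimeline:
        return GestationalTimeline(
            conception_reference=self.conception_reference,
            delivery_date=self.delivery_date,
            **self.timeline_kwargs,
        )
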