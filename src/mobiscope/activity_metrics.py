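"""Physical-activity outcomes from classified activity intervals.

Inputs are pre-classified bouts (gait / active / other) with a MET
intensity and a step count; raw accelerometer processing is out of scope.

Per day, the pipeline (a) clips all bouts to the 07:00–21:00 local window,
prorating steps, (b) discards days with under 9 h of total registration,
(c) sums the duration of gait/active bouts above 3 METs (strict) into
Active-&-Gait Time (AGT) and the steps into a daily count, (d) rescales
both to a nominal 12-h day, and (e) averages scaled values over valid
days per participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, time, timedelta
from typing import Iterable, Sequence

import numpy as np

ACTIVITY_CLASSES = ("gait", "active", "other")
WINDOW_START = time(7, 0)
WINDOW_END = time(21, 0)
MIN_VALID_HOURS = 9.0
MET_THRESHOLD = 3.0
SCALE_TARGET_HOURS = 12.0


@dataclass(frozen=True)
class ActivityInterval:
    """A classified activity bout within one local day."""

    start: datetime
    end: datetime
    activity_class: str
    intensity_met: float
    steps: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval end {self.end} not after start {self.start}")
        if self.activity_class not in ACTIVITY_CLASSES:
            raise ValueError(f"unknown activity class {self.activity_class!r}")
        if self.intensity_met < 0:
            raise ValueError("intensity_met must be >= 0")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.steps and self.activity_class == "other":
            raise ValueError("steps require a gait or active bout")

    @property
    def hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass
class ActivityDayMetrics:
    """Per-day activity outcomes; scaled values are NaN on invalid days."""

    participant_id: str
    date: _date
    registration_hours: float
    agt_raw_h: float
    steps_raw: float
    agt_scaled_h: float
    steps_scaled: float
    valid: bool


@dataclass
class ActivitySummary:
    """Participant-level mean scaled AGT/Steps over valid days."""

    participant_id: str
    agt_h: float
    steps: float
    n_valid_days: int
    valid: bool


def check_no_overlap(intervals: Sequence[ActivityInterval]) -> None:
    """Raise if any two intervals of the (single-day) list overlap."""
    ordered = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping intervals: [{a.start}, {a.end}) and [{b.start}, {b.end})"
            )


def clip_to_window(
    intervals: Iterable[ActivityInterval],
    window_start: time = WINDOW_START,
    window_end: time = WINDOW_END,
) -> list[ActivityInterval]:
    """Truncate bouts to the daytime window, prorating steps linearly.

    Bouts entirely outside the window are dropped.  Idempotent.
    """
    out: list[ActivityInterval] = []
    for iv in intervals:
        day = iv.start.date()
        lo = datetime.combine(day, window_start, tzinfo=iv.start.tzinfo)
        hi = datetime.combine(day, window_end, tzinfo=iv.start.tzinfo)
        s, e = max(iv.start, lo), min(iv.end, hi)
        if e <= s:
            continue
        frac = (e - s).total_seconds() / (iv.end - iv.start).total_seconds()
        out.append(ActivityInterval(s, e, iv.activity_class,
                                    iv.intensity_met, iv.steps * frac))
    return out


def registration_hours(intervals: Iterable[ActivityInterval]) -> float:
    """Total covered hours across all activity classes (clipped input)."""
    return float(sum(iv.hours for iv in intervals))


def is_valid_day(reg_hours: float, min_hours: float = MIN_VALID_HOURS) -> bool:
    """A day counts when at least ``min_hours`` (inclusive) were registered."""
    return reg_hours >= min_hours


def daily_agt(intervals: Iterable[ActivityInterval]) -> float:
    """Hours of gait/active bouts strictly above the 3-MET threshold."""
    return float(sum(
        iv.hours for iv in intervals
        if iv.activity_class in ("gait", "active") and iv.intensity_met > MET_THRESHOLD
    ))


def daily_steps(intervals: Iterable[ActivityInterval]) -> float:
    """Total steps over all retained (clipped) bouts."""
    return float(sum(iv.steps for iv in intervals))


def scale_to_12h(value: float, reg_hours: float) -> float:
    """Rescale a daily value to a nominal 12-h day: value * 12 / hours."""
    if reg_hours <= 0:
        raise ValueError("registration hours must be positive for scaling")
    return value * (SCALE_TARGET_HOURS / reg_hours)


def compute_day_metrics(
    participant_id: str,
    day: _date,
    intervals: Sequence[ActivityInterval],
    min_hours: float = MIN_VALID_HOURS,
) -> ActivityDayMetrics:
    """Clip, validate and summarise one day of activity bouts."""
    check_no_overlap(intervals)
    clipped = clip_to_window(intervals)
    reg = registration_hours(clipped)
    agt = daily_agt(clipped)
    steps = daily_steps(clipped)
    valid = is_valid_day(reg, min_hours)
    return ActivityDayMetrics(
        participant_id=participant_id,
        date=day,
        registration_hours=reg,
        agt_raw_h=agt,
        steps_raw=steps,
        agt_scaled_h=scale_to_12h(agt, reg) if valid else float("nan"),
        steps_scaled=scale_to_12h(steps, reg) if valid else float("nan"),
        valid=valid,
    )


def summarize_activity(days: Sequence[ActivityDayMetrics]) -> ActivitySummary:
    """Average scaled AGT/Steps over valid days; flag when none exist."""
    pid = days[0].participant_id if days else ""
    valid_days = [d for d in days if d.valid]
    if not valid_days:
        return ActivitySummary(pid, float("nan"), float("nan"), 0, False)
    return ActivitySummary(
        participant_id=pid,
        agt_h=float(np.mean([d.agt_scaled_h for d in valid_days])),
        steps=float(np.mean([d.steps_scaled for d in valid_days])),
        n_valid_days=len(valid_days),
        valid=True,
    )
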