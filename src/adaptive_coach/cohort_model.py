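"""Domain model for the coached cohort.

Patients, their prescribed weekly walking plans, daily measured activity, and
the SMS message catalog (four daily feedback messages plus the weekly
summary/achievement messages).  Goal arithmetic used by both policies and by
message rendering lives here.

Conventions
-----------
* Weeks start on **Monday**; dates are calendar dates in the patient's local
  time.
* Expected weekly accrual is uniform over the 7 days of the week: by the end
  of day *k* of the week (1-based) a patient is expected to have completed
  ``k/7`` of the weekly target.
* ``percent_of_goal`` rounds half up and is *not* clamped at 100.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ActivityPlan",
    "Patient",
    "ActivityDay",
    "DailyMessage",
    "WeeklyMessage",
    "week_start",
    "cumulative_week_minutes",
    "percent_of_goal",
    "expected_fraction",
    "render_daily_message",
    "render_weekly_message",
    "load_cohort",
    "save_cohort",
    "load_activity",
    "save_activity",
]


class DailyMessage(enum.IntEnum):
    """The four daily feedback actions.

    The integer values fix the position of each action in the one-hot action
    block of the learner's design matrix; do not reorder.
    """

    NEGATIVE = 0        # performance-avoidance framing
    POSITIVE_SELF = 1   # mastery framing
    POSITIVE_SOCIAL = 2 # performance-approach framing
    NONE = 3            # deliberate no-message day


class WeeklyMessage(enum.Enum):
    """Weekly summary catalog: a fixed reminder plus four achievements."""

    REMINDER = "reminder"
    MAXIMAL_INCREASE = "maximal_increase"
    SIGNIFICANT_INCREASE = "significant_increase"
    MAXIMAL_SOCIAL = "maximal_social"
    SIGNIFICANT_SOCIAL = "significant_social"

    @property
    def is_achievement(self) -> bool:
        return self is not WeeklyMessage.REMINDER


@dataclass(frozen=True)
class ActivityPlan:
    """A personal weekly walking prescription.

    The prescription is given as a number of sessions per week and minutes per
    session (e.g. at least 2 hours per week divided into 3 sessions); the
    weekly target must equal their product to within 1 minute of rounding.
    """

    weekly_target_minutes: float
    sessions_per_week: int
    minutes_per_session: float

    def __post_init__(self) -> None:
        if self.weekly_target_minutes <= 0:
            raise ValueError("weekly_target_minutes must be positive")
        if self.sessions_per_week <= 0 or int(self.sessions_per_week) != self.sessions_per_week:
            raise ValueError("sessions_per_week must be a positive integer")
        if self.minutes_per_session <= 0:
            raise ValueError("minutes_per_session must be positive")
        if abs(self.sessions_per_week * self.minutes_per_session - self.weekly_target_minutes) > 1.0:
            raise ValueError(
                "sessions_per_week * minutes_per_session must equal "
                "weekly_target_minutes within 1 minute"
            )


@dataclass(frozen=True)
class Patient:
    """One enrolled participant; ``arm`` is fixed for the patient's lifetime."""

    patient_id: str
    age: float
    gender: str  # "female" | "male"
    plan: ActivityPlan
    arm: str  # "treatment" | "control"
    enrolled_on: dt.date

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.gender not in ("female", "male"):
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.arm not in ("treatment", "control"):
            raise ValueError(f"unknown arm {self.arm!r}")


@dataclass(frozen=True)
class ActivityDay:
    """One patient-day of measured walking.

    ``minutes`` counts only contiguous walking bouts of 10 minutes or more
    (the measurement app's contract); ``cadence`` is the mean steps/min during
    walking, 0 when there was no qualifying walking. ``last_transmission`` is
    the most recent data upload known at the end of the day and drives the
    staleness guard.
    """

    patient_id: str
    date: dt.date
    minutes: float
    cadence: float
    last_transmission: dt.datetime

    def __post_init__(self) -> None:
        if self.minutes < 0:
            raise ValueError("minutes must be >= 0")
        if self.cadence < 0:
            raise ValueError("cadence must be >= 0")


def week_start(date: dt.date) -> dt.date:
    """Monday of the week containing ``date``."""
    return date - dt.timedelta(days=date.weekday())


def _check_sorted(history: Sequence[ActivityDay]) -> None:
    for a, b in zip(history, history[1:]):
        if b.date < a.date:
            raise ValueError("activity history must be sorted by date")


def cumulative_week_minutes(history: Sequence[ActivityDay], date: dt.date) -> float:
    """Minutes of qualifying activity accumulated in ``date``'s week up to and
    including ``date``.

    ``history`` must be sorted by date; days outside the window
    ``[week_start(date), date]`` are ignored; an empty window yields 0.
    """
    _check_sorted(history)
    start = week_start(date)
    return float(sum(d.minutes for d in history if start <= d.date <= date))


def percent_of_goal(week_minutes: float, plan: ActivityPlan) -> int:
    """Integer percent of the weekly goal achieved so far.

    Rounds half up; not clamped above 100 (over-achievers see >100%).
    """
    if week_minutes < 0:
        raise ValueError("week_minutes must be >= 0")
    return int(math.floor(100.0 * week_minutes / plan.weekly_target_minutes + 0.5))


def expected_fraction(plan: ActivityPlan, date: dt.date) -> float:
    """Fraction of the weekly target expected to be complete by the end of
    ``date`` under uniform accrual over the 7-day week.

    ``plan`` is accepted for interface symmetry (a session-schedule accrual
    model would need it); uniform accrual depends only on the weekday.
    """
    del plan
    return (date.weekday() + 1) / 7.0


_NEGATIVE_TEXT = (
    "You need to exercise to reach your activity goals. "
    "Please remember to exercise tomorrow"
)
_POSITIVE_SELF_TEXT = (
    "You have so far achieved {percent}% of your weekly activity goal. "
    "Your exercise level is in accordance with your plan. Keep up the good work"
)
_POSITIVE_SOCIAL_TEXT = (
    "You have so far achieved {percent}% of your weekly activity goal. "
    "You are exercising more than the average person in your group. "
    "Keep up the good work"
)

_WEEKLY_TEXTS = {
    WeeklyMessage.REMINDER: (
        "Please remember to exercise this week to reach your activity goals."
    ),
    WeeklyMessage.MAXIMAL_INCREASE: (
        "Over the past week you increased your activity more than at any previous week."
    ),
    WeeklyMessage.SIGNIFICANT_INCREASE: (
        "Over the past week you increased your activity more than most previous weeks."
    ),
    WeeklyMessage.MAXIMAL_SOCIAL: (
        "You won the first place! Last week you increased your activity more "
        "than any other participant in the experiment."
    ),
    WeeklyMessage.SIGNIFICANT_SOCIAL: (
        "Last week you increased your activity more than most participants of the experiment."
    ),
}


def render_daily_message(message: DailyMessage, percent: int | None = None) -> str:
    """Render the SMS text for a daily action; the no-message action renders
    to the empty string (no SMS is sent).

    ``percent`` is required (and must be >= 0) for the two positive messages,
    which embed the percent-of-goal figure.
    """
    if message is DailyMessage.NONE:
        return ""
    if message is DailyMessage.NEGATIVE:
        return _NEGATIVE_TEXT
    if percent is None or percent < 0:
        raise ValueError("positive messages require a nonnegative integer percent")
    template = (
        _POSITIVE_SELF_TEXT if message is DailyMessage.POSITIVE_SELF else _POSITIVE_SOCIAL_TEXT
    )
    return template.format(percent=int(percent))


def render_weekly_message(message: WeeklyMessage) -> str:
    return _WEEKLY_TEXTS[message]


# ---------------------------------------------------------------------------
# CSV interfaces

_COHORT_COLUMNS = [
    "patient_id",
    "age",
    "gender",
    "arm",
    "weekly_target_minutes",
    "sessions_per_week",
    "enrolled_on",
]


def save_cohort(patients: Iterable[Patient], path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "age": p.age,
            "gender": p.gender,
            "arm": p.arm,
            "weekly_target_minutes": p.plan.weekly_target_minutes,
            "sessions_per_week": p.plan.sessions_per_week,
            "enrolled_on": p.enrolled_on.isoformat(),
        }
        for p in patients
    ]
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)


def load_cohort(path) -> list[Patient]:
    df = pd.read_csv(path)
    patients = []
    for row in df.itertuples(index=False):
        target = float(row.weekly_target_minutes)
        sessions = int(row.sessions_per_week)
        plan = ActivityPlan(
            weekly_target_minutes=target,
            sessions_per_week=sessions,
            minutes_per_session=target / sessions,
        )
        patients.append(
            Patient(
                patient_id=str(row.patient_id),
                age=float(row.age),
                gender=str(row.gender),
                plan=plan,
                arm=str(row.arm),
                enrolled_on=dt.date.fromisoformat(str(row.enrolled_on)),
            )
        )
    return patients


def save_activity(days: Iterable[ActivityDay], path) -> None:
    rows = [
        {
            "patient_id": d.patient_id,
            "date": d.date.isoformat(),
            "minutes": d.minutes,
            "cadence": d.cadence,
            "last_transmission": d.last_transmission.isoformat(),
        }
        for d in days
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "date", "minutes", "cadence", "last_transmission"]
    ).to_csv(path, index=False)


def load_activity(path) -> list[ActivityDay]:
    df = pd.read_csv(path)
    return [
        ActivityDay(
            patient_id=str(r.patient_id),
            date=dt.date.fromisoformat(str(r.date)),
            minutes=float(r.minutes),
            cadence=float(r.cadence),
            last_transmission=dt.datetime.fromisoformat(str(r.last_transmission)),
        )
        for r in df.itertuples(index=False)
    ]
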