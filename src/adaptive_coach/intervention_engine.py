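"""Daily orchestration of the messaging loop.

Each morning, for every treatment-arm patient the engine: checks the
12-hour staleness guard (no SMS when no device data arrived recently),
selects the day's message with the initial policy during the burn-in phase
or the learned policy afterwards, renders and logs the SMS, and — once the
following day's data arrive — finalizes the previous decision's reward and
emits the training example.  Weekly summaries are scheduled once per week
with a 3-week cooldown on achievement messages.  Control-arm patients never
receive daily messages and get only the fixed weekly reminder.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import initial_policy
from .cohort_model import (
    ActivityDay,
    DailyMessage,
    Patient,
    WeeklyMessage,
    cumulative_week_minutes,
    expected_fraction,
    percent_of_goal,
    render_daily_message,
    render_weekly_message,
    week_start,
)
from .learned_policy import (
    ActivityResponseModel,
    ActivityResponseResults,
    FeatureVector,
    InsufficientDataError,
    TrainingExample,
    boltzmann_sample,
    build_features,
    compute_reward,
    expand_interactions,
    kesler_augment,
)

__all__ = [
    "EngineConfig",
    "DecisionRecord",
    "EngineError",
    "staleness_guard",
    "InterventionEngine",
]

logger = logging.getLogger(__name__)


class EngineError(RuntimeError):
    pass


@dataclass
class EngineConfig:
    """Knobs of the daily loop; defaults are the deployed study settings."""

    initial_phase_days: int = 90          # 3-month burn-in on the initial policy
    staleness_hours: float = 12.0         # suppress SMS when data this old or older
    achievement_cooldown_days: int = 21   # at most one achievement per 3 weeks
    temperature: float = 5.0              # Boltzmann T, fixed for the whole run
    p_no_message: float = 0.20            # initial policy's no-message rate
    min_training_examples: int = 200      # learned phase needs at least this many
    days_since_horizon: int = 30          # cap on the days-since-message features
    reward_epsilon: float = 1.0           # minutes; regularizes zero-activity days
    winsorize_cap: float = 10.0           # reward cap applied before fitting
    ridge: float = 1e-6
    decision_hour: int = 8                # local time of the morning decision
    weekly_summary_weekday: int = 0       # Monday
    policy_mode: str = "model"            # "model" | "uniform" (evaluation baseline)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.initial_phase_days, self.achievement_cooldown_days) <= 0:
            raise ValueError("durations must be positive")
        if self.staleness_hours <= 0 or self.temperature <= 0:
            raise ValueError("durations must be positive")
        if self.policy_mode not in ("model", "uniform"):
            raise ValueError("policy_mode must be 'model' or 'uniform'")


@dataclass
class DecisionRecord:
    """One morning decision for one patient; ``reward`` is filled in the next
    morning once fresh data for the response day has arrived."""

    patient_id: str
    date: dt.date
    phase: str                    # "initial" | "learned"
    action: DailyMessage
    sent: bool
    suppression_reason: str       # "none" | "stale_data" | "control_arm"
    rendered_text: str
    reward: float | None = None
    features: FeatureVector | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.suppression_reason != "none" and self.sent:
            raise ValueError("suppressed decisions cannot be marked sent")


def staleness_guard(
    last_transmission: dt.datetime | None,
    decision_time: dt.datetime,
    staleness_hours: float = 12.0,
) -> bool:
    """True when the SMS must be suppressed: no data ever received, or the
    most recent upload is ``staleness_hours`` or more old (inclusive)."""
    if last_transmission is None:
        return True
    if last_transmission > decision_time:
        raise ValueError("last_transmission lies in the future")
    age_h = (decision_time - last_transmission).total_seconds() / 3600.0
    return age_h >= staleness_hours


class InterventionEngine:
    """Stateful daily loop over a cohort.

    Feed observed :class:`ActivityDay` records with :meth:`ingest` and call
    :meth:`run_day` once per calendar date, in order.  All decision,
    training and weekly-summary state is kept on the engine and exportable
    as DataFrames/CSV; model refits are snapshotted per day for the
    stability trace.
    """

    def __init__(
        self,
        patients: Sequence[Patient],
        config: EngineConfig | None = None,
        start_date: dt.date | None = None,
    ) -> None:
        self.config = config or EngineConfig()
        self.patients = list(patients)
        self.by_id = {p.patient_id: p for p in self.patients}
        self.start_date = start_date or min(p.enrolled_on for p in self.patients)
        self.rng = np.random.default_rng([self.config.rng_seed, 777])
        self._initial_cfg = initial_policy.InitialPolicyConfig(
            p_no_message=self.config.p_no_message
        )

        self.history: dict[str, list[ActivityDay]] = {p.patient_id: [] for p in self.patients}
        self._by_date: dict[str, dict[dt.date, ActivityDay]] = {
            p.patient_id: {} for p in self.patients
        }
        self.decisions: list[DecisionRecord] = []
        self._decision_index: dict[tuple[str, dt.date], DecisionRecord] = {}
        self.message_log: dict[str, list[tuple[dt.date, DailyMessage]]] = {
            p.patient_id: [] for p in self.patients
        }
        self.examples: list[TrainingExample] = []
        self._design_rows: list[np.ndarray] = []
        self._rewards: list[float] = []
        self._example_meta: list[tuple[str, dt.date]] = []
        self.snapshots: list[ActivityResponseResults] = []
        self.results: ActivityResponseResults | None = None
        self.weekly_log: list[dict] = []
        self._last_achievement: dict[str, dt.date] = {}
        self._decided: set[dt.date] = set()

    # -- data ingestion -----------------------------------------------------
    def ingest(self, days: Iterable[ActivityDay]) -> None:
        for day in days:
            if day.patient_id not in self.by_id:
                raise EngineError(f"unknown patient {day.patient_id}")
            self.history[day.patient_id].append(day)
            self._by_date[day.patient_id][day.date] = day
        for pid in self.history:
            self.history[pid].sort(key=lambda d: d.date)

    def _minutes_on(self, pid: str, date: dt.date) -> float | None:
        day = self._by_date[pid].get(date)
        return None if day is None else day.minutes

    def _last_transmission(self, pid: str, before: dt.datetime) -> dt.datetime | None:
        ts = [d.last_transmission for d in self.history[pid] if d.last_transmission <= before]
        return max(ts) if ts else None

    # -- phases and rewards -------------------------------------------------
    def phase_on(self, date: dt.date) -> str:
        day_number = (date - self.start_date).days
        if day_number >= self.config.initial_phase_days and (
            len(self.examples) >= self.config.min_training_examples
        ):
            return "learned"
        return "initial"

    def _finalize_rewards(self, date: dt.date, decision_time: dt.datetime) -> None:
        """Finalize decisions dated ``date - 1``: their response day is
        yesterday, so with fresh data the reward (yesterday over the day
        before) is now computable and, for executed decisions, becomes a
        training example."""
        target = date - dt.timedelta(days=1)
        for patient in self.patients:
            pid = patient.patient_id
            rec = self._decision_index.get((pid, target))
            if rec is None or rec.reward is not None:
                continue
            resp = self._by_date[pid].get(target)
            prev = self._minutes_on(pid, target - dt.timedelta(days=1))
            if resp is None or prev is None:
                continue
            if staleness_guard(resp.last_transmission, decision_time, self.config.staleness_hours):
                continue  # data for the gap never counts; no example either
            rec.reward = compute_reward(prev, resp.minutes, self.config.reward_epsilon)
            if rec.sent and rec.features is not None:
                ex = TrainingExample(features=rec.features, action=rec.action, reward=rec.reward)
                self.examples.append(ex)
                self._design_rows.append(
                    expand_interactions(kesler_augment(rec.features, rec.action))
                )
                self._rewards.append(rec.reward)
                self._example_meta.append((pid, rec.date))

    def _refit(self, date: dt.date) -> None:
        model = ActivityResponseModel(
            design=np.vstack(self._design_rows),
            rewards=np.array(self._rewards),
            ridge=self.config.ridge,
            winsorize_cap=self.config.winsorize_cap,
            min_examples=self.config.min_training_examples,
        )
        self.results = model.fit(fit_date=date)
        self.snapshots.append(self.results)

    # -- the daily loop ------------------------------------------------------
    def run_day(self, date: dt.date) -> list[DecisionRecord]:
        if date in self._decided:
            raise EngineError(f"run_day already executed for {date}")
        decision_time = dt.datetime.combine(date, dt.time(self.config.decision_hour, 0))

        self._finalize_rewards(date, decision_time)
        phase = self.phase_on(date)
        if phase == "learned" and self.config.policy_mode == "model":
            try:
                self._refit(date)
            except InsufficientDataError:  # pragma: no cover - phase_on guards this
                phase = "initial"

        records: list[DecisionRecord] = []
        for patient in self.patients:
            pid = patient.patient_id
            if patient.arm == "control":
                rec = DecisionRecord(
                    patient_id=pid,
                    date=date,
                    phase=phase,
                    action=DailyMessage.NONE,
                    sent=False,
                    suppression_reason="control_arm",
                    rendered_text="",
                )
                records.append(rec)
                continue

            last_tx = self._last_transmission(pid, decision_time)
            if staleness_guard(last_tx, decision_time, self.config.staleness_hours):
                rec = DecisionRecord(
                    patient_id=pid,
                    date=date,
                    phase=phase,
                    action=DailyMessage.NONE,
                    sent=False,
                    suppression_reason="stale_data",
                    rendered_text="",
                )
                records.append(rec)
                continue

            features = build_features(
                patient,
                self.history[pid],
                self.message_log[pid],
                date - dt.timedelta(days=1),
                horizon=self.config.days_since_horizon,
            )
            if phase == "learned":
                if self.config.policy_mode == "uniform":
                    action = DailyMessage(int(self.rng.integers(4)))
                else:
                    gains = self.results.action_gains(features)
                    action = boltzmann_sample(gains, self.config.temperature, self.rng)
            else:
                f = expected_fraction(patient.plan, date)
                action = initial_policy.choose_action(f, self.rng, self._initial_cfg)

            percent = percent_of_goal(features.cumulative_week_minutes, patient.plan)
            rec = DecisionRecord(
                patient_id=pid,
                date=date,
                phase=phase,
                action=action,
                sent=True,
                suppression_reason="none",
                rendered_text=render_daily_message(action, percent),
                features=features,
            )
            self.message_log[pid].append((date, action))
            records.append(rec)

        for rec in records:
            self._decision_index[(rec.patient_id, rec.date)] = rec
        self.decisions.extend(records)
        self._decided.add(date)

        if date.weekday() == self.config.weekly_summary_weekday and date > self.start_date:
            for patient in self.patients:
                msg = self.weekly_summary(patient, date)
                self.weekly_log.append(
                    {
                        "patient_id": patient.patient_id,
                        "date": date,
                        "message": msg.value,
                        "text": render_weekly_message(msg),
                    }
                )

        logger.info(
            "%s: %d decisions (%s phase), %d training examples",
            date,
            len(records),
            phase,
            len(self.examples),
        )
        return records

    # -- weekly summaries ----------------------------------------------------
    def _weekly_totals(self, pid: str, date: dt.date) -> list[float]:
        """Minutes per completed week (weeks strictly before ``date``'s week),
        from enrollment onward."""
        current = week_start(date)
        totals: dict[dt.date, float] = {}
        for day in self.history[pid]:
            w = week_start(day.date)
            if w < current:
                totals[w] = totals.get(w, 0.0) + day.minutes
        if not totals:
            return []
        weeks = sorted(totals)
        first, last = weeks[0], weeks[-1]
        out = []
        w = first
        while w <= last:
            out.append(totals.get(w, 0.0))
            w += dt.timedelta(days=7)
        return out

    def _current_increase(self, pid: str, date: dt.date) -> float | None:
        totals = self._weekly_totals(pid, date)
        if len(totals) < 2:
            return None
        return totals[-1] - totals[-2]

    def weekly_summary(self, patient: Patient, date: dt.date) -> WeeklyMessage:
        """Choose the weekly message for the week starting at ``date``.

        "Increase" is this completed week's minutes minus the previous
        completed week's.  Achievements require an eligible increase, at
        least one *previous* weekly increase to compare against, and the
        3-week cooldown to have elapsed; precedence is maximal increase >
        maximal social > significant increase > significant social, with the
        "significant" variants thresholded at the median of the comparison
        set.  Control-arm patients always get the fixed reminder.
        """
        if patient.arm == "control":
            return WeeklyMessage.REMINDER
        pid = patient.patient_id
        last_ach = self._last_achievement.get(pid)
        if last_ach is not None and (date - last_ach).days < self.config.achievement_cooldown_days:
            return WeeklyMessage.REMINDER

        totals = self._weekly_totals(pid, date)
        if len(totals) < 2:
            return WeeklyMessage.REMINDER
        increases = [b - a for a, b in zip(totals, totals[1:])]
        current = increases[-1]
        previous = increases[:-1]

        others = [
            inc
            for other in self.patients
            if other.patient_id != pid
            for inc in [self._current_increase(other.patient_id, date)]
            if inc is not None
        ]

        chosen: WeeklyMessage | None = None
        if previous and current > max(previous):
            chosen = WeeklyMessage.MAXIMAL_INCREASE
        elif others and current > max(others):
            chosen = WeeklyMessage.MAXIMAL_SOCIAL
        elif previous and current > statistics.median(previous):
            chosen = WeeklyMessage.SIGNIFICANT_INCREASE
        elif others and current > statistics.median(others):
            chosen = WeeklyMessage.SIGNIFICANT_SOCIAL

        if chosen is None:
            return WeeklyMessage.REMINDER
        self._last_achievement[pid] = date
        return chosen

    # -- exports -------------------------------------------------------------
    def decision_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": r.patient_id,
                "date": r.date.isoformat(),
                "phase": r.phase,
                "action": r.action.name.lower(),
                "sent": r.sent,
                "suppression_reason": r.suppression_reason,
                "rendered_text": r.rendered_text,
                "reward": r.reward,
            }
            for r in self.decisions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "date",
                "phase",
                "action",
                "sent",
                "suppression_reason",
                "rendered_text",
                "reward",
            ],
        )

    def training_frame(self) -> pd.DataFrame:
        rows = []
        for (pid, date), ex in zip(self._example_meta, self.examples):
            rows.append(
                {
                    "patient_id": pid,
                    "date": date.isoformat(),
                    "features": json.dumps(ex.features.to_array().tolist()),
                    "action": ex.action.name.lower(),
                    "reward": ex.reward,
                }
            )
        return pd.DataFrame(rows, columns=["patient_id", "date", "features", "action", "reward"])

    def weekly_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weekly_log, columns=["patient_id", "date", "message", "text"])

    def activity_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": d.patient_id,
                "date": d.date.isoformat(),
                "minutes": d.minutes,
                "cadence": d.cadence,
                "last_transmission": d.last_transmission.isoformat(),
            }
            for days in self.history.values()
            for d in days
        ]
        return pd.DataFrame(
            rows, columns=["patient_id", "date", "minutes", "cadence", "last_transmission"]
        ).sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
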