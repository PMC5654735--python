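"""Synthetic cohort and daily behavior model.

Generates a cohort of sedentary patients with personal weekly walking plans
(mean 139, SD 62 min/week) and simulates their day-to-day walking under the
message policies, with the statistical structure the closed loop needs to be
testable without real data:

* three latent response clusters (sizes in a 4:9:5 ratio): cluster 1 reacts
  negatively to any message, cluster 2 reacts weakly, cluster 3 reacts
  positively with the social-comparison message strongest;
* a gender-by-cluster association (cluster 3 male-dominated, cluster 2
  female-dominated) so a single shared model can partially personalize;
* sequence effects keyed by (previous message, current message);
* occasional transmission gaps that exercise the 12-hour staleness guard;
* scheduled cohort-wide behavior shocks (e.g. adverse weather) that depress
  everyone's baseline for a window of days.

The behavior model is multiplicative-lognormal: cluster effect, sequence
effect, slow adherence drift, shock attenuation and day noise all compose by
multiplication on a per-patient baseline, matching the ratio form of the
learner's reward.  Daily totals are quantized to whole minutes and totals
under 10 minutes record as 0 (only contiguous walks of 10+ minutes count).

Behavioral noise is drawn from a per-(patient, day) stream keyed only by the
master seed, so two policy arms replayed on the same seed face identical
worlds (common random numbers) and differ only through their actions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_model import ActivityDay, ActivityPlan, DailyMessage, Patient

__all__ = [
    "SimulatorConfig",
    "LatentPatientState",
    "generate_cohort",
    "simulate_day",
    "shock_severity_on",
    "apply_shock",
    "CohortSimulator",
    "hba1c_trajectory",
]

_DEFAULT_CLUSTER_MULTIPLIERS = {
    # (negative, positive_self, positive_social, none), DailyMessage order
    1: (0.5, 0.6, 0.6, 1.0),
    2: (0.9, 1.0, 1.1, 1.0),
    3: (1.0, 1.4, 1.8, 0.8),
}


def _default_sequence_multipliers() -> np.ndarray:
    seq = np.ones((4, 4))
    seq[DailyMessage.NEGATIVE, DailyMessage.POSITIVE_SELF] = 1.2
    seq[DailyMessage.POSITIVE_SOCIAL, DailyMessage.POSITIVE_SOCIAL] = 0.8
    return seq


@dataclass
class SimulatorConfig:
    """Study-condition defaults for the synthetic cohort.

    Cohort sizes, the plan distribution, the cluster mixture and the gender
    mix match the study design being emulated; effect sizes, noise scales and
    the shock schedule are stated modelling choices (see the methods note).
    """

    n_treatment: int = 20
    n_control: int = 7
    plan_mean: float = 139.0           # weekly target minutes
    plan_sd: float = 62.0
    plan_min: float = 30.0
    sessions_per_week: int = 3
    cluster_weights: tuple[float, float, float] = (4.0, 9.0, 5.0)
    p_female_given_cluster: tuple[float, float, float] = (0.5, 2.0 / 3.0, 0.2)
    cluster_multipliers: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_CLUSTER_MULTIPLIERS.items()}
    )
    sequence_multipliers: np.ndarray = field(default_factory=_default_sequence_multipliers)
    baseline_dispersion: float = 0.3   # lognormal sigma of patient-level baseline
    noise_sd: float = 0.3              # lognormal sigma of day-to-day noise
    drift_sd: float = 0.0005           # SD of per-day multiplicative adherence drift
    cadence_mean: float = 95.0         # steps/min
    cadence_sd: float = 10.0
    cadence_coupling: float = 0.3      # exponent tying cadence to the activity multiplier
    cadence_noise_sd: float = 0.05
    transmission_gap_prob: float = 0.05
    shock_schedule: tuple[tuple[int, int, float], ...] = ((60, 5, 0.6),)
    age_mean: float = 57.0
    age_sd: float = 8.0
    hba1c_mean: float = 7.8
    hba1c_sd: float = 1.0
    hba1c_coef_per_weekly_minute: float = 0.002  # %-points over a 26-week course
    start_date: dt.date = dt.date(2016, 1, 4)    # a Monday
    additive_model: bool = False       # additive (rather than multiplicative) effects
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatment <= 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be positive")
        w = np.asarray(self.cluster_weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("cluster mixture weights must be nonnegative and sum > 0")
        self.sequence_multipliers = np.asarray(self.sequence_multipliers, dtype=float)
        if self.sequence_multipliers.shape != (4, 4):
            raise ValueError("sequence_multipliers must be 4x4")
        for s in (self.baseline_dispersion, self.noise_sd, self.drift_sd, self.cadence_noise_sd):
            if s < 0:
                raise ValueError("standard deviations must be >= 0")

    @property
    def cluster_probs(self) -> np.ndarray:
        w = np.asarray(self.cluster_weights, dtype=float)
        return w / w.sum()


@dataclass
class LatentPatientState:
    """Hidden truth for one synthetic patient; never exposed to the policies."""

    patient_id: str
    cluster: int                 # 1, 2 or 3
    baseline_minutes: float      # expected daily minutes absent any message
    baseline_cadence: float      # steps/min
    drift_slope: float           # per-day log-scale adherence drift
    baseline_hba1c: float
    last_message: DailyMessage = DailyMessage.NONE


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    # rejection sampling; the truncation point is far enough into the body
    # that this terminates quickly for all default configurations
    while True:
        v = rng.normal(mean, sd)
        if v >= lower:
            return float(v)


def _plan_location(mean: float, sd: float, lower: float) -> float:
    """Location parameter of a lower-truncated normal whose *truncated* mean
    equals ``mean``; found by bisection so the configured plan mean is the
    mean of the plans actually drawn."""
    from scipy.stats import truncnorm

    def truncated_mean(loc: float) -> float:
        a = (lower - loc) / sd
        return float(truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    lo, hi = mean - 3 * sd, mean
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if truncated_mean(mid) > mean:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def generate_cohort(
    config: SimulatorConfig, rng: np.random.Generator
) -> tuple[list[Patient], dict[str, LatentPatientState]]:
    """Draw a cohort of patients with plans and latent response structure.

    Plans are truncated-normal (mean/SD from config, floor ``plan_min``) and
    rounded so the session count times session length reproduces the weekly
    target exactly.  Cluster labels come from the configured mixture and
    gender is drawn conditional on cluster.
    """
    n_total = config.n_treatment + config.n_control
    patients: list[Patient] = []
    states: dict[str, LatentPatientState] = {}
    probs = config.cluster_probs
    plan_loc = _plan_location(config.plan_mean, config.plan_sd, config.plan_min)
    for i in range(n_total):
        pid = f"p{i + 1:03d}"
        arm = "treatment" if i < config.n_treatment else "control"
        target_raw = _truncated_normal(rng, plan_loc, config.plan_sd, config.plan_min)
        per_session = max(10.0, round(target_raw / config.sessions_per_week))
        target = per_session * config.sessions_per_week
        plan = ActivityPlan(
            weekly_target_minutes=target,
            sessions_per_week=config.sessions_per_week,
            minutes_per_session=per_session,
        )
        cluster = int(rng.choice(3, p=probs)) + 1
        gender = "female" if rng.random() < config.p_female_given_cluster[cluster - 1] else "male"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 35.0, 80.0))
        patients.append(
            Patient(
                patient_id=pid,
                age=age,
                gender=gender,
                plan=plan,
                arm=arm,
                enrolled_on=config.start_date,
            )
        )
        states[pid] = LatentPatientState(
            patient_id=pid,
            cluster=cluster,
            baseline_minutes=(target / 7.0) * rng.lognormal(0.0, config.baseline_dispersion),
            baseline_cadence=_truncated_normal(rng, config.cadence_mean, config.cadence_sd, 60.0),
            drift_slope=rng.normal(0.0, config.drift_sd),
            baseline_hba1c=_truncated_normal(rng, config.hba1c_mean, config.hba1c_sd, 5.5),
        )
    return patients, states


def shock_severity_on(day_index: int, schedule: Sequence[tuple[int, int, float]]) -> float:
    """Severity of any scheduled shock active on ``day_index`` (0 if none)."""
    for start, duration, severity in schedule:
        if not 0.0 <= severity <= 1.0:
            raise ValueError("shock severity must lie in [0, 1]")
        if start <= day_index < start + duration:
            return severity
    return 0.0


def apply_shock(
    states: dict[str, LatentPatientState], severity: float
) -> dict[str, LatentPatientState]:
    """Return shock-attenuated copies of the latent states (baselines scaled
    by ``1 - severity``); the originals are untouched so behavior restores
    after the window."""
    if not 0.0 <= severity <= 1.0:
        raise ValueError("shock severity must lie in [0, 1]")
    return {
        pid: replace(s, baseline_minutes=s.baseline_minutes * (1.0 - severity))
        for pid, s in states.items()
    }


def simulate_day(
    state: LatentPatientState,
    action: DailyMessage,
    date: dt.date,
    day_index: int,
    rng: np.random.Generator,
    config: SimulatorConfig,
    prev_transmission: dt.datetime | None = None,
    shock_severity: float = 0.0,
) -> ActivityDay:
    """Simulate one patient-day of walking under ``action``.

    Consumes a fixed number of random draws in a fixed order regardless of
    the action, so a per-(patient, day) stream yields identical noise across
    policy arms.  ``state.last_message`` supplies the sequence effect and is
    updated to ``action``.
    """
    noise = rng.lognormal(0.0, config.noise_sd) if config.noise_sd > 0 else 1.0
    cadence_noise = (
        rng.lognormal(0.0, config.cadence_noise_sd) if config.cadence_noise_sd > 0 else 1.0
    )
    gap_draw = rng.random()

    mult = config.cluster_multipliers[state.cluster][int(action)]
    seq = float(config.sequence_multipliers[int(state.last_message), int(action)])
    drift = float(np.exp(state.drift_slope * day_index))
    base = state.baseline_minutes * drift * (1.0 - shock_severity)
    if config.additive_model:
        raw = base + base * (mult - 1.0) + base * (seq - 1.0)
        raw = max(0.0, raw) * noise
    else:
        raw = base * mult * seq * noise
    minutes = float(round(raw))
    if minutes < 10.0:  # sub-bout-threshold days record as no activity
        minutes = 0.0

    if minutes > 0:
        cadence = state.baseline_cadence * (mult ** config.cadence_coupling) * cadence_noise
        cadence = float(max(0.0, cadence))
    else:
        cadence = 0.0

    # the app uploads every 2.5 h while the phone is reachable; we record the
    # final upload of the day, or carry the previous timestamp on a gap day
    upload = dt.datetime.combine(date, dt.time(22, 0))
    if gap_draw < config.transmission_gap_prob and prev_transmission is not None:
        last_transmission = prev_transmission
    else:
        last_transmission = upload

    state.last_message = action
    return ActivityDay(
        patient_id=state.patient_id,
        date=date,
        minutes=minutes,
        cadence=cadence,
        last_transmission=last_transmission,
    )


class CohortSimulator:
    """Stateful wrapper holding the cohort, latent truth, and noise streams.

    Noise for (patient i, day d) comes from ``default_rng([seed, i, d])``, so
    the world is a deterministic function of the master seed alone.
    """

    def __init__(self, config: SimulatorConfig | None = None, seed: int | None = None):
        self.config = config or SimulatorConfig()
        self.seed = self.config.rng_seed if seed is None else seed
        cohort_rng = np.random.default_rng([self.seed, 12345])
        self.patients, self.states = generate_cohort(self.config, cohort_rng)
        self._index = {p.patient_id: i for i, p in enumerate(self.patients)}
        self._last_transmission: dict[str, dt.datetime | None] = {
            p.patient_id: None for p in self.patients
        }

    def day_rng(self, patient_id: str, day_index: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, self._index[patient_id], day_index])

    def step(self, patient_id: str, action: DailyMessage, day_index: int) -> ActivityDay:
        """Simulate ``day_index`` (0-based from the start date) for one patient."""
        date = self.config.start_date + dt.timedelta(days=day_index)
        severity = shock_severity_on(day_index, self.config.shock_schedule)
        day = simulate_day(
            self.states[patient_id],
            action,
            date,
            day_index,
            self.day_rng(patient_id, day_index),
            self.config,
            prev_transmission=self._last_transmission[patient_id],
            shock_severity=severity,
        )
        self._last_transmission[patient_id] = day.last_transmission
        return day

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": s.patient_id,
                    "cluster": s.cluster,
                    "baseline_minutes": s.baseline_minutes,
                    "baseline_cadence": s.baseline_cadence,
                    "drift_slope": s.drift_slope,
                    "baseline_hba1c": s.baseline_hba1c,
                }
                for s in self.states.values()
            ]
        )


def hba1c_trajectory(
    state: LatentPatientState,
    mean_weekly_minutes: float,
    weeks_elapsed: float,
    config: SimulatorConfig,
) -> float:
    """Latent glycated-hemoglobin value after ``weeks_elapsed`` weeks.

    Improvement is linear in the patient's average weekly activity, scaled so
    the configured coefficient is the full improvement over a 26-week course:
    ``h = h0 - coef * mean_weekly_minutes * weeks/26``.  A demo channel for
    the relative-reduction analysis, not a physiological claim.
    """
    return state.baseline_hba1c - (
        config.hba1c_coef_per_weekly_minute * mean_weekly_minutes * weeks_elapsed / 26.0
    )
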