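import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from adaptive_coach import run_closed_loop
from adaptive_coach.cohort_model import ActivityDay, ActivityPlan, Patient
from adaptive_coach.intervention_engine import EngineConfig

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

MONDAY = dt.date(2016, 1, 4)  # the simulator's default start date, a Monday


@pytest.fixture
def plan():
    return ActivityPlan(weekly_target_minutes=140.0, sessions_per_week=3, minutes_per_session=140.0 / 3)


@pytest.fixture
def make_patient(plan):
    def _make(pid="p001", age=58.0, gender="male", arm="treatment", plan_=None, enrolled=MONDAY):
        return Patient(
            patient_id=pid,
            age=age,
            gender=gender,
            plan=plan_ or plan,
            arm=arm,
            enrolled_on=enrolled,
        )

    return _make


def make_day(pid, date, minutes, cadence=95.0, tx_hour=22):
    return ActivityDay(
        patient_id=pid,
        date=date,
        minutes=minutes,
        cadence=cadence if minutes > 0 else 0.0,
        last_transmission=dt.datetime.combine(date, dt.time(tx_hour, 0)),
    )


@pytest.fixture(scope="session")
def loop_result():
    """A medium closed-loop run shared by engine and evaluation tests: the
    default 27-patient cohort for 60 days with a 30-day burn-in, so both
    policy phases are exercised."""
    cfg = EngineConfig(initial_phase_days=30)
    return run_closed_loop(engine_config=cfg, n_days=60, seed=11)
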