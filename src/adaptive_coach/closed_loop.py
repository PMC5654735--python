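"""Wiring between the synthetic cohort simulator and the intervention engine.

Runs the full loop — morning decisions, simulated behavior, next-morning
reward bookkeeping — for a configured number of days, deterministically for
a given master seed.  The same seed replayed against the "uniform" policy
mode faces an identical simulated world (common random numbers), so policy
comparisons are paired.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import pandas as pd

from .intervention_engine import EngineConfig, InterventionEngine
from .patient_simulator import CohortSimulator, SimulatorConfig

__all__ = ["ClosedLoopResult", "run_closed_loop"]


@dataclass
class ClosedLoopResult:
    simulator: CohortSimulator
    engine: InterventionEngine
    n_days: int

    @property
    def decisions(self) -> pd.DataFrame:
        return self.engine.decision_frame()

    @property
    def activity(self) -> pd.DataFrame:
        return self.engine.activity_frame()

    def mean_reward(self, phase: str | None = None, arm: str = "treatment") -> float:
        """Mean finalized reward over decisions, optionally restricted to a
        phase; control-arm decisions are excluded by default."""
        ids = {p.patient_id for p in self.engine.patients if p.arm == arm}
        vals = [
            r.reward
            for r in self.engine.decisions
            if r.reward is not None
            and r.patient_id in ids
            and (phase is None or r.phase == phase)
        ]
        if not vals:
            raise ValueError("no finalized rewards in the requested slice")
        return float(sum(vals) / len(vals))


def run_closed_loop(
    sim_config: SimulatorConfig | None = None,
    engine_config: EngineConfig | None = None,
    n_days: int = 180,
    seed: int = 0,
    policy_mode: str | None = None,
) -> ClosedLoopResult:
    """Simulate ``n_days`` of the coached cohort under one master seed.

    ``policy_mode`` overrides the engine's learned-phase behavior ("model"
    for the Boltzmann-sampled learned policy, "uniform" for the random
    comparison arm).  All randomness — cohort generation, behavior noise,
    and policy draws — derives from ``seed``.
    """
    sim_config = replace(sim_config or SimulatorConfig(), rng_seed=seed)
    engine_config = engine_config or EngineConfig()
    engine_config = replace(engine_config, rng_seed=seed)
    if policy_mode is not None:
        engine_config = replace(engine_config, policy_mode=policy_mode)

    sim = CohortSimulator(sim_config)
    engine = InterventionEngine(sim.patients, engine_config, start_date=sim_config.start_date)

    for day_index in range(n_days):
        date = sim_config.start_date + dt.timedelta(days=day_index)
        records = engine.run_day(date)
        by_pid = {r.patient_id: r for r in records}
        observed = [
            sim.step(p.patient_id, by_pid[p.patient_id].action, day_index)
            for p in sim.patients
        ]
        engine.ingest(observed)

    return ClosedLoopResult(simulator=sim, engine=engine, n_days=n_days)
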