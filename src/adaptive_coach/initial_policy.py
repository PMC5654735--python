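"""The predetermined stochastic message policy used during the burn-in phase.

On 20% of patient-days (i.i.d. Bernoulli) no message is sent.  On the
remaining days a uniform random number u ~ U(0, 1) is drawn and compared with
the fraction of the weekly activity target expected to be complete on that
day: if u is strictly larger the patient receives the negative message,
otherwise one of the two positive messages with equal probability.  The tie
u == f goes to a positive message ("larger than" is strict); this is a
measure-zero event but the convention is fixed for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_model import DailyMessage

__all__ = ["InitialPolicyConfig", "action_distribution", "choose_action"]


@dataclass(frozen=True)
class InitialPolicyConfig:
    p_no_message: float = 0.20
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_no_message <= 1.0:
            raise ValueError("p_no_message must lie in [0, 1]")


def action_distribution(
    f: float, config: InitialPolicyConfig = InitialPolicyConfig()
) -> np.ndarray:
    """Analytic action probabilities of the initial policy.

    Integrating the uniform threshold draw gives, for expected fraction ``f``::

        P(none)            = p_no_message
        P(negative)        = (1 - p_no_message) * (1 - f)
        P(positive_self)   = (1 - p_no_message) * f / 2
        P(positive_social) = (1 - p_no_message) * f / 2

    Returns a length-4 vector indexed by :class:`DailyMessage`.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("expected fraction f must lie in [0, 1]")
    p = config.p_no_message
    probs = np.zeros(4)
    probs[DailyMessage.NONE] = p
    probs[DailyMessage.NEGATIVE] = (1.0 - p) * (1.0 - f)
    probs[DailyMessage.POSITIVE_SELF] = (1.0 - p) * f / 2.0
    probs[DailyMessage.POSITIVE_SOCIAL] = (1.0 - p) * f / 2.0
    return probs


def choose_action(
    f: float,
    rng: np.random.Generator,
    config: InitialPolicyConfig = InitialPolicyConfig(),
) -> DailyMessage:
    """Sample one daily action from the initial policy.

    The draws follow the policy's narrative order (no-message Bernoulli first,
    then the uniform threshold, then the positive coin flip), which is
    distributionally identical to a single categorical draw from
    :func:`action_distribution`.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("expected fraction f must lie in [0, 1]")
    if rng.random() < config.p_no_message:
        return DailyMessage.NONE
    if rng.random() > f:
        return DailyMessage.NEGATIVE
    return DailyMessage.POSITIVE_SELF if rng.random() < 0.5 else DailyMessage.POSITIVE_SOCIAL
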