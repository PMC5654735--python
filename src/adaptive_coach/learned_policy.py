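"""Contextual-bandit learner for daily message selection.

The learner treats message choice as a contextual bandit: each morning a
per-patient context vector x is built from activity, demographics and message
history; the four possible messages are encoded by augmenting x with a
one-hot action block (the Kesler construction for multiclass problems); a
single linear regression **with all pairwise interactions** is refit daily on
every (context, action, reward) triple collected so far; and the next action
is drawn by Boltzmann (softmax) sampling over the four predicted rewards at a
fixed temperature T = 5, which keeps every message's probability comfortably
above 10% for predicted next-day activity ratios in their realistic range.

The reward for the action taken after observing day *t* is the day-over-day
activity ratio ``y = minutes(t+1) / minutes(t)``, regularized by a small
epsilon so zero-activity days remain defined, and winsorized at a cap before
fitting to bound the leverage of near-zero denominators.

The regression itself is ridge-stabilized ordinary least squares on the
interaction-expanded design (lambda = 1e-6 on the normal equations, intercept
unpenalized); with the sample sizes reached after the burn-in phase it is
numerically indistinguishable from plain least squares but remains defined
while the design is still rank-deficient early on.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort_model import (
    ActivityDay,
    DailyMessage,
    Patient,
    cumulative_week_minutes,
    expected_fraction,
    week_start,
)

__all__ = [
    "FeatureVector",
    "TrainingExample",
    "InsufficientDataError",
    "FEATURE_NAMES",
    "ACTION_NAMES",
    "compute_reward",
    "build_features",
    "kesler_augment",
    "interaction_manifest",
    "expand_interactions",
    "ActivityResponseModel",
    "ActivityResponseResults",
    "predict_gain",
    "boltzmann_probabilities",
    "boltzmann_sample",
]

#: Names of the 10 numeric context features, in design-matrix order.
FEATURE_NAMES = [
    "minutes_last_day",
    "cumulative_week_minutes",
    "fraction_of_goal",
    "fraction_vs_expected",
    "age",
    "gender_female",
    "days_since_negative",
    "days_since_positive_self",
    "days_since_positive_social",
    "days_since_none",
]

#: Names of the 4 one-hot action indicators, ordered by DailyMessage value.
ACTION_NAMES = [
    "action_negative",
    "action_positive_self",
    "action_positive_social",
    "action_none",
]

_N_FEATURES = len(FEATURE_NAMES)
_N_ACTIONS = len(ACTION_NAMES)
_N_BASE = _N_FEATURES + _N_ACTIONS


class InsufficientDataError(RuntimeError):
    """Raised when too few training examples exist to fit the model; the
    engine stays on the initial policy until this stops being raised."""


@dataclass(frozen=True)
class FeatureVector:
    """Per-patient-day context x as seen at the morning decision time.

    All activity-derived fields refer to the most recent fully observed day
    (the day before the decision).  ``days_since_message`` counts mornings
    since each of the four actions was last executed, so its minimum possible
    value at decision time is 1 (sent the previous morning); types never sent
    are capped at the configured horizon.
    """

    minutes_last_day: float
    cumulative_week_minutes: float
    fraction_of_goal: float
    fraction_vs_expected: float
    age: float
    gender_female: int
    days_since_message: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature vector contains non-finite values")
        if any(d < 1 for d in self.days_since_message):
            raise ValueError("days_since_message entries must be >= 1")

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.minutes_last_day,
                self.cumulative_week_minutes,
                self.fraction_of_goal,
                self.fraction_vs_expected,
                self.age,
                float(self.gender_female),
                *[float(d) for d in self.days_since_message],
            ]
        )


@dataclass(frozen=True)
class TrainingExample:
    """One (context, action, reward) triple the learner fits on."""

    features: FeatureVector
    action: DailyMessage
    reward: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.reward) or self.reward < 0:
            raise ValueError("reward must be finite and >= 0")


def compute_reward(minutes_t: float, minutes_next: float, epsilon: float = 1.0) -> float:
    """Day-over-day activity ratio ``(minutes_next + eps) / (minutes_t + eps)``.

    With ``epsilon=0`` this is the raw ratio of next-day to same-day walking
    minutes (> 1 means activity increased); the default ``epsilon=1`` minute
    keeps the ratio defined on zero-activity days.
    """
    if minutes_t < 0 or minutes_next < 0:
        raise ValueError("minutes must be >= 0")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    return (minutes_next + epsilon) / (minutes_t + epsilon)


def build_features(
    patient: Patient,
    history: Sequence[ActivityDay],
    message_log: Iterable[tuple[dt.date, DailyMessage]],
    date: dt.date,
    horizon: int = 30,
) -> FeatureVector:
    """Build the context vector as of the morning after ``date``.

    ``date`` is the most recent fully observed day: ``minutes_last_day`` and
    the weekly accrual features are computed through the end of ``date``, and
    the decision the features feed happens the following morning.
    ``message_log`` lists (date, action) pairs of previously *executed*
    decisions; suppressed days do not appear.
    """
    if patient.plan is None:  # pragma: no cover - dataclass forbids this
        raise ValueError("patient has no activity plan")
    by_date = {d.date: d for d in history if d.patient_id == patient.patient_id}
    last = by_date.get(date)
    minutes_last = last.minutes if last is not None else 0.0

    week_minutes = cumulative_week_minutes(
        sorted((d for d in history if d.patient_id == patient.patient_id), key=lambda d: d.date),
        date,
    )
    target = patient.plan.weekly_target_minutes
    frac_goal = week_minutes / target
    frac_vs_expected = frac_goal / expected_fraction(patient.plan, date)

    decision_date = date + dt.timedelta(days=1)
    last_sent: dict[DailyMessage, dt.date] = {}
    for d, action in message_log:
        if d < decision_date:
            prev = last_sent.get(action)
            if prev is None or d > prev:
                last_sent[action] = d
    days_since = []
    for action in DailyMessage:
        sent_on = last_sent.get(action)
        if sent_on is None:
            days_since.append(horizon)
        else:
            days_since.append(max(1, min(horizon, (decision_date - sent_on).days)))

    return FeatureVector(
        minutes_last_day=minutes_last,
        cumulative_week_minutes=week_minutes,
        fraction_of_goal=frac_goal,
        fraction_vs_expected=frac_vs_expected,
        age=patient.age,
        gender_female=1 if patient.gender == "female" else 0,
        days_since_message=tuple(days_since),
    )


def kesler_augment(x: FeatureVector | np.ndarray, action: DailyMessage) -> np.ndarray:
    """Concatenate the 10 numeric features with the one-hot action block.

    The j-th action entry is 1 iff message j (in :class:`DailyMessage` order)
    was sent; the result has 14 entries.
    """
    base = x.to_array() if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    if base.shape != (_N_FEATURES,):
        raise ValueError(f"expected {_N_FEATURES} numeric features, got {base.shape}")
    onehot = np.zeros(_N_ACTIONS)
    onehot[int(action)] = 1.0
    return np.concatenate([base, onehot])


def _interaction_pairs() -> list[tuple[int, int]]:
    """Index pairs (i < j) for pairwise products, excluding pairs where both
    columns are action indicators (their product is structurally zero for a
    one-hot block)."""
    pairs = []
    for i in range(_N_BASE):
        for j in range(i + 1, _N_BASE):
            if i >= _N_FEATURES and j >= _N_FEATURES:
                continue
            pairs.append((i, j))
    return pairs


_PAIRS = _interaction_pairs()
_PAIR_I = np.array([p[0] for p in _PAIRS])
_PAIR_J = np.array([p[1] for p in _PAIRS])


def interaction_manifest() -> list[str]:
    """Deterministic column names of the interaction-expanded design: the 14
    main effects followed by the retained pairwise products."""
    base = FEATURE_NAMES + ACTION_NAMES
    names = list(base)
    names.extend(f"{base[i]}*{base[j]}" for i, j in _PAIRS)
    return names


def expand_interactions(rows: np.ndarray) -> np.ndarray:
    """Expand augmented row(s) into the full interaction design.

    Accepts one row of length 14 or a matrix (n, 14); returns the main
    effects followed by all pairwise products of distinct columns except
    action x action products, 99 columns in total, in manifest order.
    """
    arr = np.asarray(rows, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if arr.shape[1] != _N_BASE:
        raise ValueError(f"expected {_N_BASE} base columns, got {arr.shape[1]}")
    design = np.hstack([arr, arr[:, _PAIR_I] * arr[:, _PAIR_J]])
    return design[0] if squeeze else design


@dataclass
class ActivityResponseResults:
    """Fitted daily-refit regression: coefficients over the interaction
    design, their standard errors, and fit diagnostics.

    Behaves like a statsmodels results object at small scale: ``params``
    (without intercept), ``intercept``, ``bse``, ``rsquared_adj``, ``nobs``,
    ``summary()``, plus JSON snapshot round-tripping for the day-to-day
    stability trace.
    """

    intercept: float
    params: np.ndarray
    bse: np.ndarray
    intercept_se: float
    manifest: list[str]
    nobs: int
    rsquared_adj: float
    rsquared: float
    fit_date: dt.date | None = None
    #: full covariance of (intercept, params); kept in memory for contrast
    #: inference, not serialized into snapshots
    cov_params: np.ndarray | None = field(default=None, repr=False)

    def predict_design(self, design: np.ndarray) -> np.ndarray:
        design = np.atleast_2d(np.asarray(design, dtype=float))
        if design.shape[1] != len(self.params):
            raise ValueError("design width does not match fitted manifest")
        return self.intercept + design @ self.params

    def predict_gain(self, x: FeatureVector, action: DailyMessage) -> float:
        """Predicted next-day activity ratio for taking ``action`` in context ``x``."""
        row = expand_interactions(kesler_augment(x, action))
        return float(self.predict_design(row)[0])

    def action_gains(self, x: FeatureVector) -> np.ndarray:
        """Predicted ratio for each of the four actions, in DailyMessage order."""
        rows = np.stack([expand_interactions(kesler_augment(x, a)) for a in DailyMessage])
        return self.predict_design(rows)

    def summary(self, top: int = 10) -> str:
        order = np.argsort(-np.abs(self.params))[:top]
        lines = [
            "Activity response model (interaction-expanded least squares)",
            f"  n obs: {self.nobs}   columns: {len(self.params)}",
            f"  R^2: {self.rsquared:.4f}   adj. R^2: {self.rsquared_adj:.4f}",
            f"  intercept: {self.intercept:+.4f} (se {self.intercept_se:.4f})",
            f"  largest coefficients:",
        ]
        for k in order:
            lines.append(
                f"    {self.manifest[k]:<55s} {self.params[k]:+.4f} (se {self.bse[k]:.4f})"
            )
        return "\n".join(lines)

    # -- snapshots ----------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "params": self.params.tolist(),
                "bse": self.bse.tolist(),
                "intercept_se": self.intercept_se,
                "manifest": self.manifest,
                "nobs": self.nobs,
                "rsquared": self.rsquared,
                "rsquared_adj": self.rsquared_adj,
                "fit_date": self.fit_date.isoformat() if self.fit_date else None,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ActivityResponseResults":
        d = json.loads(payload)
        return cls(
            intercept=d["intercept"],
            params=np.array(d["params"]),
            bse=np.array(d["bse"]),
            intercept_se=d["intercept_se"],
            manifest=list(d["manifest"]),
            nobs=int(d["nobs"]),
            rsquared=float(d["rsquared"]),
            rsquared_adj=float(d["rsquared_adj"]),
            fit_date=dt.date.fromisoformat(d["fit_date"]) if d["fit_date"] else None,
        )


class ActivityResponseModel:
    """The daily-refit interaction regression, statsmodels-style.

    Construct from training examples (or a prebuilt design) and call
    :meth:`fit`; refitting on identical data reproduces identical
    coefficients.

    Parameters
    ----------
    examples:
        (context, action, reward) triples collected so far.
    ridge:
        Tikhonov penalty added to the normal equations (intercept excluded);
        stabilizes the early, rank-deficient regime and is negligible once a
        few hundred examples exist.
    winsorize_cap:
        Rewards above this cap are clipped before fitting; ratio rewards are
        heavy-tailed when the denominator day had near-zero activity.
    min_examples:
        Below this count :meth:`fit` raises :class:`InsufficientDataError`.
    """

    def __init__(
        self,
        examples: Sequence[TrainingExample] | None = None,
        *,
        design: np.ndarray | None = None,
        rewards: np.ndarray | None = None,
        ridge: float = 1e-6,
        winsorize_cap: float = 10.0,
        min_examples: int = 200,
    ) -> None:
        if examples is not None:
            rows = np.stack(
                [kesler_augment(ex.features, ex.action) for ex in examples]
            ) if examples else np.empty((0, _N_BASE))
            design = expand_interactions(rows) if len(rows) else np.empty((0, len(interaction_manifest())))
            rewards = np.array([ex.reward for ex in examples])
        if design is None or rewards is None:
            raise ValueError("provide examples, or design and rewards")
        self.design = np.atleast_2d(np.asarray(design, dtype=float))
        self.rewards = np.asarray(rewards, dtype=float)
        self.ridge = ridge
        self.winsorize_cap = winsorize_cap
        self.min_examples = min_examples
        # restricted designs (e.g. small oracle instances) get generic names
        width = self.design.shape[1]
        full = interaction_manifest()
        self.manifest = full if width == len(full) else [f"c{i}" for i in range(width)]

    def fit(self, fit_date: dt.date | None = None) -> ActivityResponseResults:
        n = len(self.rewards)
        if n < self.min_examples:
            raise InsufficientDataError(
                f"{n} examples < minimum {self.min_examples}; stay on the initial policy"
            )
        y = np.minimum(self.rewards, self.winsorize_cap)
        X = np.column_stack([np.ones(n), self.design])
        k = X.shape[1]
        penalty = np.eye(k) * self.ridge
        penalty[0, 0] = 0.0  # intercept unpenalized
        xtx = X.T @ X + penalty
        beta = np.linalg.solve(xtx, X.T @ y)

        resid = y - X @ beta
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        p = X.shape[1] - 1  # predictors excluding intercept
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        dof = n - p - 1
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else float("nan")
        sigma2 = rss / dof if dof > 0 else float("nan")
        cov = sigma2 * np.linalg.inv(xtx)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))

        return ActivityResponseResults(
            intercept=float(beta[0]),
            params=beta[1:],
            bse=se[1:],
            intercept_se=float(se[0]),
            manifest=self.manifest,
            nobs=n,
            rsquared=r2,
            rsquared_adj=adj_r2,
            fit_date=fit_date,
            cov_params=cov,
        )


def predict_gain(
    results: ActivityResponseResults, x: FeatureVector, action: DailyMessage
) -> float:
    """Functional alias for :meth:`ActivityResponseResults.predict_gain`."""
    return results.predict_gain(x, action)


def boltzmann_probabilities(gains: np.ndarray, temperature: float = 5.0) -> np.ndarray:
    """Softmax selection probabilities ``exp(g_a/T) / sum_b exp(g_b/T)``.

    The maximum gain is subtracted before exponentiation; the distribution is
    invariant to shifting all gains by a constant, so this only provides
    numerical stability.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    g = np.asarray(gains, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gains must be finite")
    z = (g - g.max()) / temperature
    w = np.exp(z)
    return w / w.sum()


def boltzmann_sample(
    gains: np.ndarray, temperature: float, rng: np.random.Generator
) -> DailyMessage:
    """Sample a daily action from the Boltzmann distribution over the four
    predicted gains (DailyMessage order)."""
    probs = boltzmann_probabilities(gains, temperature)
    if probs.shape != (_N_ACTIONS,):
        raise ValueError("expected one gain per daily action")
    return DailyMessage(int(rng.choice(_N_ACTIONS, p=probs)))
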