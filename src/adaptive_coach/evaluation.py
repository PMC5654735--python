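"""Results-style analyses over decision logs.

Operates on the engine's decision log (real-format or simulated): per-message
effectiveness, sequential (previous-day x current-day) effects, k-means
clustering of per-patient response vectors, fit-weighted activity and cadence
slopes, the day-to-day model stability / adjusted-R-squared traces, and the
relative HbA1c reduction statistic.

The decision log is a DataFrame with columns ``patient_id, date, phase,
action, sent, suppression_reason, rendered_text, reward`` (as written by
:meth:`InterventionEngine.decision_frame`).  Analyses of message response use
only executed decisions (``sent``) with finalized rewards.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .cohort_model import DailyMessage
from .learned_policy import ActivityResponseResults

__all__ = [
    "ResponseVector",
    "SlopeEstimate",
    "ACTION_ORDER",
    "feedback_effectiveness",
    "sequential_effects",
    "response_vectors",
    "cluster_responses",
    "ClusteringResult",
    "activity_slope",
    "cadence_slope",
    "weighted_mean_slope",
    "model_trace",
    "relative_hba1c_reduction",
    "evaluate_log",
]

ACTION_ORDER = [m.name.lower() for m in DailyMessage]


@dataclass(frozen=True)
class ResponseVector:
    """Per-patient mean activity change following each daily message.

    Only patients who received at least two distinct message types qualify
    for the clustering analysis.
    """

    patient_id: str
    means: tuple[float | None, float | None, float | None, float | None]
    counts: tuple[int, int, int, int]

    @property
    def n_distinct(self) -> int:
        return sum(1 for c in self.counts if c > 0)


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope of a per-patient series with its fit-quality weight (the
    regression's R-squared, clamped to [0, 1])."""

    patient_id: str
    slope: float
    weight: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


def _finalized(log: pd.DataFrame) -> pd.DataFrame:
    out = log[(log["sent"]) & log["reward"].notna()].copy()
    return out


def feedback_effectiveness(log: pd.DataFrame) -> dict:
    """Per-message mean improvement and probability-weighted effectiveness.

    For each policy phase: the mean reward following each message, the
    empirical send frequency of each message, and their inner product (the
    feedback effectiveness).  Messages never sent in a phase are reported as
    missing (None), not zero.
    """
    rows = _finalized(log)
    report: dict = {}
    for phase, grp in rows.groupby("phase"):
        n = len(grp)
        means: dict[str, float | None] = {}
        freqs: dict[str, float] = {}
        effectiveness = 0.0
        for action in ACTION_ORDER:
            sub = grp[grp["action"] == action]
            freqs[action] = len(sub) / n if n else 0.0
            if len(sub):
                m = float(sub["reward"].mean())
                means[action] = m
                effectiveness += freqs[action] * m
            else:
                means[action] = None
        report[phase] = {
            "mean_improvement": means,
            "frequency": freqs,
            "effectiveness": effectiveness if n else None,
            "n": n,
        }
    return report


def sequential_effects(log: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean change in activity by (previous-day message, current message).

    Only strictly consecutive patient-days (one calendar day apart) form
    pairs; returns (means, counts) as 4x4 DataFrames indexed by previous
    action.  Descriptive, not causal: pairs reflect whatever the policy chose.
    """
    rows = _finalized(log).copy()
    rows["date"] = pd.to_datetime(rows["date"])
    sums = pd.DataFrame(0.0, index=ACTION_ORDER, columns=ACTION_ORDER)
    counts = pd.DataFrame(0, index=ACTION_ORDER, columns=ACTION_ORDER)
    for _, grp in rows.groupby("patient_id"):
        grp = grp.sort_values("date")
        prev = grp.shift(1)
        mask = (grp["date"] - prev["date"]).dt.days == 1
        for p_action, c_action, reward in zip(
            prev.loc[mask, "action"], grp.loc[mask, "action"], grp.loc[mask, "reward"]
        ):
            sums.loc[p_action, c_action] += reward
            counts.loc[p_action, c_action] += 1
    means = sums / counts.replace(0, np.nan)
    return means, counts


def response_vectors(log: pd.DataFrame, min_distinct: int = 2) -> list[ResponseVector]:
    """Per-patient mean reward following each message, keeping only patients
    who received at least ``min_distinct`` different message types."""
    rows = _finalized(log)
    out = []
    for pid, grp in rows.groupby("patient_id"):
        means = []
        counts = []
        for action in ACTION_ORDER:
            sub = grp[grp["action"] == action]
            counts.append(len(sub))
            means.append(float(sub["reward"].mean()) if len(sub) else None)
        vec = ResponseVector(patient_id=str(pid), means=tuple(means), counts=tuple(counts))
        if vec.n_distinct >= min_distinct:
            out.append(vec)
    return out


@dataclass
class ClusteringResult:
    patient_ids: list[str]
    labels: np.ndarray          # 1-based, ascending in centroid mean response
    centroids: np.ndarray       # (k, 4), rows in label order
    inertia: float
    degenerate: bool            # all response vectors identical

    def ari(self, truth: Sequence[int]) -> float:
        return float(adjusted_rand_score(list(truth), list(self.labels)))


def cluster_responses(
    vectors: Sequence[ResponseVector],
    k: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> ClusteringResult:
    """k-means over the 4-dimensional response vectors.

    Entries for messages a patient never received are filled with that
    patient's mean response over received messages (a neutral value for that
    patient).  Clusters are relabeled so label 1 has the most negative mean
    response and label k the most positive, making labels deterministic and
    comparable across runs.
    """
    if len(vectors) < k:
        raise ValueError(f"need at least k={k} eligible patients, got {len(vectors)}")
    X = np.zeros((len(vectors), 4))
    for i, vec in enumerate(vectors):
        present = [m for m in vec.means if m is not None]
        fill = float(np.mean(present))
        X[i] = [m if m is not None else fill for m in vec.means]

    degenerate = bool(np.allclose(X, X[0]))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    order = np.argsort(km.cluster_centers_.mean(axis=1))  # ascending mean response
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = np.array([relabel[int(r)] for r in raw])
    centroids = km.cluster_centers_[order]
    return ClusteringResult(
        patient_ids=[v.patient_id for v in vectors],
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
        degenerate=degenerate,
    )


def activity_slope(series: Sequence[float], patient_id: str = "") -> SlopeEstimate:
    """OLS slope of a daily fraction-of-target series against day index,
    weighted by the fit's R-squared."""
    y = np.asarray(series, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 points to fit a slope")
    x = np.arange(len(y), dtype=float)
    res = stats.linregress(x, y)
    weight = float(np.clip(res.rvalue**2, 0.0, 1.0)) if np.isfinite(res.rvalue) else 0.0
    return SlopeEstimate(patient_id=patient_id, slope=float(res.slope), weight=weight, n=len(y))


def cadence_slope(weekly_series: Sequence[float], patient_id: str = "") -> SlopeEstimate:
    """As :func:`activity_slope`, on weekly mean steps-per-minute.  Weeks with
    no walking (cadence undefined) must be excluded by the caller; zeros here
    are treated as data."""
    return activity_slope(weekly_series, patient_id=patient_id)


def weighted_mean_slope(estimates: Sequence[SlopeEstimate]) -> float:
    """Group mean slope, weighted by each participant's fit quality."""
    if not estimates:
        raise ValueError("no slope estimates")
    w = np.array([e.weight for e in estimates])
    s = np.array([e.slope for e in estimates])
    if w.sum() == 0:
        return float(np.mean(s))
    return float(np.sum(w * s) / np.sum(w))


def model_trace(snapshots: Sequence[ActivityResponseResults]) -> pd.DataFrame:
    """Day-to-day stability and adjusted-R-squared traces from daily model
    snapshots.

    stability(d) = sum_j | |beta_j(d)| - |beta_j(d-1)| | over all coefficients
    (intercept included); a sign flip with unchanged magnitude contributes 0.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least 2 snapshots")
    manifests = {tuple(s.manifest) for s in snapshots}
    if len(manifests) != 1:
        raise ValueError("snapshots have mismatched column manifests")
    rows = []
    prev = None
    for snap in snapshots:
        beta = np.concatenate([[snap.intercept], snap.params])
        stability = float(np.sum(np.abs(np.abs(beta) - np.abs(prev)))) if prev is not None else np.nan
        rows.append(
            {
                "fit_date": snap.fit_date,
                "stability": stability,
                "rsquared_adj": snap.rsquared_adj,
                "nobs": snap.nobs,
            }
        )
        prev = beta
    return pd.DataFrame(rows)


def relative_hba1c_reduction(h0: float, ht: float) -> float:
    """Relative reduction in glycated hemoglobin, ``(h0 - ht) / h0``; positive
    values mean improved glycemic control."""
    if h0 <= 0:
        raise ValueError("baseline HbA1c must be positive")
    return (h0 - ht) / h0


def evaluate_log(
    log: pd.DataFrame,
    activity: pd.DataFrame | None = None,
    cohort: pd.DataFrame | None = None,
    snapshots: Sequence[ActivityResponseResults] | None = None,
    cluster_seed: int = 0,
) -> dict:
    """Produce the full JSON-serializable evaluation report for a run.

    Includes the effectiveness tables, the sequential-effects matrix (labelled
    descriptive, since message pairs were chosen by the policy rather than at
    random), response clustering when enough eligible patients exist,
    fit-weighted group slopes when activity and cohort tables are supplied,
    and the model traces when snapshots are supplied.
    """
    report: dict = {"feedback_effectiveness": feedback_effectiveness(log)}
    means, counts = sequential_effects(log)
    report["sequential_effects"] = {
        "note": "descriptive: message pairs reflect policy choices, not randomization",
        "mean": means.where(pd.notna(means), None).values.tolist(),
        "counts": counts.values.tolist(),
        "actions": ACTION_ORDER,
    }
    vectors = response_vectors(log)
    if len(vectors) >= 3:
        clustering = cluster_responses(vectors, k=3, seed=cluster_seed)
        report["clusters"] = {
            "patient_ids": clustering.patient_ids,
            "labels": clustering.labels.tolist(),
            "centroids": clustering.centroids.tolist(),
            "degenerate": clustering.degenerate,
        }

    if activity is not None and cohort is not None:
        act = activity.copy()
        act["date"] = pd.to_datetime(act["date"])
        targets = cohort.set_index("patient_id")["weekly_target_minutes"]
        arms = cohort.set_index("patient_id")["arm"]
        group_slopes: dict[str, list[SlopeEstimate]] = {}
        cadence_slopes: dict[str, list[SlopeEstimate]] = {}
        for pid, grp in act.groupby("patient_id"):
            grp = grp.sort_values("date")
            daily_target = float(targets.loc[pid]) / 7.0
            frac = (grp["minutes"] / daily_target).to_numpy()
            if len(frac) < 2:
                continue
            arm = str(arms.loc[pid])
            group_slopes.setdefault(arm, []).append(activity_slope(frac, patient_id=str(pid)))
            weekly = (
                grp[grp["cadence"] > 0]
                .groupby(grp["date"].dt.to_period("W"))["cadence"]
                .mean()
            )
            if len(weekly) >= 2:
                cadence_slopes.setdefault(arm, []).append(
                    cadence_slope(weekly.to_numpy(), patient_id=str(pid))
                )
        report["activity_slopes"] = {
            arm: {
                "weighted_mean_slope": weighted_mean_slope(ests),
                "n": len(ests),
            }
            for arm, ests in group_slopes.items()
        }
        report["cadence_slopes"] = {
            arm: {
                "weighted_mean_slope": weighted_mean_slope(ests),
                "n": len(ests),
            }
            for arm, ests in cadence_slopes.items()
        }

    if snapshots and len(snapshots) >= 2:
        trace = model_trace(snapshots)
        report["model_trace"] = {
            "fit_date": [d.isoformat() if d else None for d in trace["fit_date"]],
            "stability": [None if pd.isna(v) else float(v) for v in trace["stability"]],
            "rsquared_adj": [float(v) for v in trace["rsquared_adj"]],
        }
    return report
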