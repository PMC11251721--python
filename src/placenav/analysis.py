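"""Session aggregation and the condition-comparison workflow.

Aggregates per-trial metrics into session summaries, applies the
phase-specific training criteria, locates the PRE/POST learning windows,
merges the two vehicle-control (PBS) sessions after a per-metric
no-difference gate, and runs the scalar (repeated-measures ANOVA) and
angular (Watson–Williams + Kuiper) condition contrasts.

Two visit-percentage denominators are reported: ``high_visit_pct`` uses
all trials (timeouts count against it), while the training criteria use
completed trials only.  Angular contrasts pool trials across subjects;
scalar contrasts are subject-level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import Session
from .circstats import (
    ALPHA,
    CircularTestResult,
    MeanVector,
    RMAnovaResult,
    WW_APPLICABILITY_THRESHOLD,
    kuiper_two_sample,
    mean_vector,
    rm_anova,
    watson_williams,
    wilcoxon_signed_rank,
)
from .environment import ArenaConfig
from .metrics import TrialMetrics, compute_trial_metrics

__all__ = [
    "SessionSummary",
    "CriteriaReport",
    "PrePostSplit",
    "MergePBSResult",
    "ConditionReport",
    "summarize_session",
    "evaluate_criteria",
    "find_pre_post",
    "merge_pbs",
    "compare_conditions",
    "SCALAR_METRICS",
]

PHASES = ("shaping", "pre_training", "post_training", "probe")

#: Scalar session metrics eligible for subject-level contrasts.
SCALAR_METRICS = (
    "high_visit_pct",
    "mean_speed",
    "mean_crossings",
    "dd_vector_length",
    "pcd_vector_length",
    "mean_dd_deviation",
    "mean_pcd_deviation",
    "session_duration",
    "n_trials",
)


@dataclass
class SessionSummary:
    subject_id: str
    condition: str
    day: int
    n_trials: int
    n_completed: int
    high_visit_pct: float            # denominator = all trials
    high_visit_pct_completed: float  # denominator = completed trials
    low_visit_pct: float
    timeout_pct: float
    mean_speed: float                # cm/s
    mean_crossings: float
    dd_mean_vector: MeanVector
    pcd_mean_vector: MeanVector
    mean_dd_deviation: float
    mean_pcd_deviation: float
    mean_excess: float
    session_duration: float          # s, including ITIs
    dd_angles: np.ndarray            # pooled per-trial DDs (defined ones)
    pcd_angles: np.ndarray

    @property
    def dd_vector_length(self) -> float:
        return self.dd_mean_vector.length

    @property
    def pcd_vector_length(self) -> float:
        return self.pcd_mean_vector.length


def get_metric(summary: SessionSummary, name: str) -> float:
    return float(getattr(summary, name))


def summarize_session(
    session: Session,
    config: ArenaConfig,
    metrics: list[TrialMetrics] | None = None,
) -> SessionSummary:
    """Aggregate a session's per-trial metrics into a summary record.

    Session duration is reconstructed as the sum of trial latencies plus
    one ITI stillness period between consecutive trials.
    """
    if len(session.trials) == 0:
        raise ValueError("cannot summarize an empty session")
    if metrics is None:
        metrics = [compute_trial_metrics(tr, config) for tr in session.trials]

    n = len(metrics)
    outcomes = [m.outcome for m in metrics]
    n_high = outcomes.count("high")
    n_low = outcomes.count("low")
    n_timeout = outcomes.count("timeout")
    n_completed = n - n_timeout

    dd = np.array([m.departing_direction for m in metrics if m.departing_direction is not None])
    pcd = np.array(
        [m.perimeter_crossing_direction for m in metrics if m.perimeter_crossing_direction is not None]
    )
    ddd = [m.dd_deviation for m in metrics if m.dd_deviation is not None]
    pcdd = [m.pcd_deviation for m in metrics if m.pcd_deviation is not None]
    excess = [m.excess_travel_distance for m in metrics if m.excess_travel_distance is not None]
    duration = sum(m.latency for m in metrics) + config.iti_still_duration * (n - 1)

    nan_mv = MeanVector(direction=float("nan"), length=0.0, n=0)
    return SessionSummary(
        subject_id=session.subject_id,
        condition=session.condition,
        day=session.day,
        n_trials=n,
        n_completed=n_completed,
        high_visit_pct=100.0 * n_high / n,
        high_visit_pct_completed=100.0 * n_high / n_completed if n_completed else 0.0,
        low_visit_pct=100.0 * n_low / n,
        timeout_pct=100.0 * n_timeout / n,
        mean_speed=float(np.mean([m.mean_speed for m in metrics])),
        mean_crossings=float(np.mean([m.n_perimeter_crossings for m in metrics])),
        dd_mean_vector=mean_vector(dd) if dd.size else nan_mv,
        pcd_mean_vector=mean_vector(pcd) if pcd.size else nan_mv,
        mean_dd_deviation=float(np.mean(ddd)) if ddd else float("nan"),
        mean_pcd_deviation=float(np.mean(pcdd)) if pcdd else float("nan"),
        mean_excess=float(np.mean(excess)) if excess else float("nan"),
        session_duration=float(duration),
        dd_angles=dd,
        pcd_angles=pcd,
    )


@dataclass
class CriteriaReport:
    phase: str
    passed: bool
    reasons: list


def evaluate_criteria(summary: SessionSummary, phase: str) -> CriteriaReport:
    """Apply the phase-specific training criteria.

    shaping: > 60 trials.  pre_training: 60 trials within 40 min, > 75%
    high-value visits (completed-trial denominator), mean excess < 0.6 m.
    post_training: 40 trials, > 75%, mean excess < 1 m.  probe: 40 trials,
    mean excess < 0.1 m (strict inequalities throughout).
    """
    reasons = []
    if phase == "shaping":
        if not summary.n_trials > 60:
            reasons.append("trial count (need > 60)")
    elif phase == "pre_training":
        if summary.n_trials < 60:
            reasons.append("trial count (need 60)")
        if summary.session_duration > 40 * 60:
            reasons.append("session duration (need 60 trials within 40 min)")
        if not summary.high_visit_pct_completed > 75.0:
            reasons.append("visit percentage (need > 75%)")
        if not summary.mean_excess < 0.6:
            reasons.append("excess travel distance (need < 0.6 m)")
    elif phase == "post_training":
        if summary.n_trials < 40:
            reasons.append("trial count (need 40)")
        if not summary.high_visit_pct_completed > 75.0:
            reasons.append("visit percentage (need > 75%)")
        if not summary.mean_excess < 1.0:
            reasons.append("excess travel distance (need < 1 m)")
    elif phase == "probe":
        if summary.n_trials < 40:
            reasons.append("trial count (need 40)")
        if not summary.mean_excess < 0.1:
            reasons.append("excess travel distance (need < 0.1 m)")
    else:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    return CriteriaReport(phase=phase, passed=not reasons, reasons=reasons)


@dataclass
class PrePostSplit:
    pre_days: tuple       # indices into the input sequence
    post_days: tuple
    pre: list             # the two PRE SessionSummary records
    post: list


def find_pre_post(daily_summaries, phase: str = "pre_training") -> PrePostSplit:
    """Locate the learning windows in a chronological day series.

    POST is the first pair of consecutive days passing the > 75%
    high-value-visit criterion; PRE is the two days immediately before.
    """
    passed = [s.high_visit_pct_completed > 75.0 for s in daily_summaries]
    post_start = None
    for i in range(len(passed) - 1):
        if passed[i] and passed[i + 1]:
            post_start = i
            break
    if post_start is None:
        raise ValueError("no pair of consecutive criterion-passing days")
    if post_start < 2:
        raise ValueError(
            "criterion reached before enough pre-learning days accumulated"
        )
    pre_days = (post_start - 2, post_start - 1)
    post_days = (post_start, post_start + 1)
    return PrePostSplit(
        pre_days=pre_days,
        post_days=post_days,
        pre=[daily_summaries[i] for i in pre_days],
        post=[daily_summaries[i] for i in post_days],
    )


def average_pair(pair, metrics=SCALAR_METRICS) -> dict:
    """Per-rat average of scalar metrics over a two-day window."""
    return {m: float(np.mean([get_metric(s, m) for s in pair])) for m in metrics}


@dataclass
class MergePBSResult:
    gate: dict            # metric -> CircularTestResult (Wilcoxon)
    merged: pd.DataFrame  # one row per subject; merged or retained columns
    refused: list         # metrics whose merge was refused


def merge_pbs(dpbs, ipbs, metrics=SCALAR_METRICS, alpha: float = ALPHA) -> MergePBSResult:
    """Merge the dPBS and iPBS control sessions after a per-metric gate.

    For each metric a Wilcoxon signed-rank test compares the paired
    sessions; if p >= alpha the per-subject average is emitted as the
    merged PBS value, otherwise the merge is refused for that metric and
    both session values are retained (columns ``dPBS_<m>``, ``iPBS_<m>``).
    """
    d_by_subject = {s.subject_id: s for s in dpbs}
    i_by_subject = {s.subject_id: s for s in ipbs}
    if set(d_by_subject) != set(i_by_subject):
        raise ValueError("dPBS and iPBS sessions are not paired by subject")
    subjects = sorted(d_by_subject)

    gate = {}
    refused = []
    cols = {"subject_id": subjects}
    for m in metrics:
        dv = np.array([get_metric(d_by_subject[s], m) for s in subjects])
        iv = np.array([get_metric(i_by_subject[s], m) for s in subjects])
        try:
            res = wilcoxon_signed_rank(dv, iv)
        except ValueError:
            # identical sessions: trivially mergeable
            res = CircularTestResult(
                statistic=0.0, df=(0,), p_value=1.0,
                method="wilcoxon_degenerate_all_ties",
                n_per_group=(len(subjects), len(subjects)),
            )
        gate[m] = res
        if res.p_value >= alpha:
            cols[m] = (dv + iv) / 2.0
        else:
            refused.append(m)
            cols[f"dPBS_{m}"] = dv
            cols[f"iPBS_{m}"] = iv
    return MergePBSResult(gate=gate, merged=pd.DataFrame(cols), refused=refused)


@dataclass
class AngularContrast:
    omnibus: CircularTestResult            # Watson–Williams across all groups
    pairwise_ww: dict                      # (a, b) -> CircularTestResult
    pairwise_kuiper: dict                  # (a, b) -> CircularTestResult
    mean_vectors: dict                     # condition -> MeanVector


@dataclass
class ConditionReport:
    conditions: tuple
    scalar: dict                           # metric -> RMAnovaResult
    angular: dict                          # "dd"/"pcd" -> AngularContrast


def compare_conditions(
    summaries_by_condition: dict,
    scalar_metrics=("high_visit_pct", "mean_speed", "mean_crossings",
                    "dd_vector_length", "pcd_vector_length",
                    "mean_dd_deviation", "mean_pcd_deviation"),
    angular: bool = True,
    n_perm: int = 2000,
    seed=0,
) -> ConditionReport:
    """Run the full condition-contrast workflow.

    Scalar metrics: one-way RM ANOVA (with Greenhouse–Geisser correction
    reported) and Bonferroni pairwise post hocs over matched subjects.
    Angular metrics: trial-pooled Watson–Williams across conditions with
    the 0.45 applicability gate, plus pairwise Kuiper and Watson–Williams
    contrasts.
    """
    conditions = tuple(summaries_by_condition)
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions to compare")
    subject_sets = [
        tuple(sorted(s.subject_id for s in summaries_by_condition[c])) for c in conditions
    ]
    if len(set(subject_sets)) != 1:
        raise ValueError("conditions have mismatched subjects")
    subjects = subject_sets[0]
    by_cond = {
        c: {s.subject_id: s for s in summaries_by_condition[c]} for c in conditions
    }

    scalar = {}
    for m in scalar_metrics:
        mat = np.array(
            [[get_metric(by_cond[c][subj], m) for c in conditions] for subj in subjects]
        )
        if np.any(~np.isfinite(mat)):
            continue
        scalar[m] = rm_anova(mat, condition_names=conditions)

    angular_out = {}
    if angular:
        for key, attr in (("dd", "dd_angles"), ("pcd", "pcd_angles")):
            pooled = {
                c: np.concatenate(
                    [getattr(s, attr) for s in summaries_by_condition[c]]
                )
                for c in conditions
            }
            if any(v.size < 2 for v in pooled.values()):
                continue
            omnibus = watson_williams([pooled[c] for c in conditions])
            mvs = {c: mean_vector(pooled[c]) for c in conditions}
            pw_ww, pw_k = {}, {}
            for i, a in enumerate(conditions):
                for b in conditions[i + 1:]:
                    pw_ww[(a, b)] = watson_williams([pooled[a], pooled[b]])
                    pw_k[(a, b)] = kuiper_two_sample(
                        pooled[a], pooled[b], n_perm=n_perm,
                        seed=[int(seed), i, conditions.index(b)],
                    )
            angular_out[key] = AngularContrast(
                omnibus=omnibus,
                pairwise_ww=pw_ww,
                pairwise_kuiper=pw_k,
                mean_vectors=mvs,
            )
    return ConditionReport(conditions=conditions, scalar=scalar, angular=angular_out)
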