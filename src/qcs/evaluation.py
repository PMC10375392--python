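"""Feasibility-trial analysis: per-trial selection errors, trial-level
confusion metrics, paired timing comparison, and Likert survey summaries.

Conventions: the confusion matrix is tallied at the *trial* level (one
participant x scenario observation is one trial), sensitivity/specificity are
percentages reported to one decimal place, Likert SDs use the sample (n-1)
denominator, and the paired t-test is two-sided. Raw values are retained
internally; rounding is display-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TrialRecord",
    "ConfusionCounts",
    "LikertItemSummary",
    "PairedTResult",
    "StudyReport",
    "EvaluationError",
    "UndefinedMetricError",
    "DegenerateTestError",
    "DEFAULT_LIKERT_BANDS",
    "classify_selection_errors",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "paired_t_test",
    "likert_summary",
    "evaluate_study",
]


class EvaluationError(ValueError):
    pass


class UndefinedMetricError(EvaluationError):
    """A rate with a zero denominator is undefined, not zero."""


class DegenerateTestError(EvaluationError):
    """Paired differences have zero variance; the t statistic is undefined."""


@dataclass(frozen=True)
class TrialRecord:
    """One participant x scenario observation.

    ``intended`` is the scenario ground truth (conditions actually present);
    ``selected`` is what the participant chose. Completion times for the two
    tools are optional and in seconds.
    """

    participant_id: str
    scenario_id: str
    selected: frozenset[str]
    intended: frozenset[str]
    truth_multimorbid: bool | None
    predicted_multimorbid: bool | None
    mmapp_time_s: float | None = None
    comparator_time_s: float | None = None

    def __post_init__(self) -> None:
        for label, value in (
            ("mmapp_time_s", self.mmapp_time_s),
            ("comparator_time_s", self.comparator_time_s),
        ):
            if value is not None and value < 0:
                raise EvaluationError(f"{label} must be nonnegative, got {value}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify_selection_errors(trial: TrialRecord) -> tuple[int, int, int]:
    """(n_correct, n_incorrect, n_missed) condition selections for one trial.

    Counts conserve: n_correct + n_missed = |intended| and
    n_correct + n_incorrect = |selected|.
    """
    correct = len(trial.selected & trial.intended)
    incorrect = len(trial.selected - trial.intended)
    missed = len(trial.intended - trial.selected)
    return correct, incorrect, missed


def confusion_counts(trials: Sequence[TrialRecord]) -> ConfusionCounts:
    """Trial-level confusion matrix over truth/predicted multimorbidity labels."""
    tp = fp = tn = fn = 0
    for trial in trials:
        if trial.truth_multimorbid is None or trial.predicted_multimorbid is None:
            raise EvaluationError(
                f"trial {trial.participant_id}/{trial.scenario_id} lacks a "
                "truth or predicted multimorbidity label"
            )
        if trial.truth_multimorbid:
            if trial.predicted_multimorbid:
                tp += 1
            else:
                fn += 1
        else:
            if trial.predicted_multimorbid:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(counts: ConfusionCounts) -> float:
    """True-positive rate as a percentage: 100*TP/(TP+FN)."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive-truth trials")
    return 100.0 * counts.tp / (counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    """True-negative rate as a percentage: 100*TN/(TN+FP)."""
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative-truth trials")
    return 100.0 * counts.tn / (counts.tn + counts.fp)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Classic paired t-test on the differences a - b, two-sided.

    Requires equal lengths >= 2 and non-degenerate differences.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.shape != b_arr.shape or a_arr.ndim != 1:
        raise EvaluationError(
            f"paired samples must be 1-D and equal length, got {a_arr.shape} vs {b_arr.shape}"
        )
    n = a_arr.size
    if n < 2:
        raise EvaluationError(f"need at least 2 pairs, got {n}")
    diffs = a_arr - b_arr
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise DegenerateTestError("paired differences have zero variance")
    result = stats.ttest_rel(a_arr, b_arr)
    return PairedTResult(t=float(result.statistic), df=n - 1, p=float(result.pvalue))


# ---------------------------------------------------------------------------
# Likert summaries

# Default interpretation banding on the item mean. Published interpretations
# of such tables are not always monotone in the mean, so the banding is a
# configuration value, not a fixed rule; this default uses symmetric
# half-point cut points around the five anchor labels.
DEFAULT_LIKERT_BANDS: tuple[tuple[float, float, str], ...] = (
    (1.0, 1.5, "Strongly disagree"),
    (1.5, 2.5, "Disagree"),
    (2.5, 3.5, "Neutral"),
    (3.5, 4.5, "Agree"),
    (4.5, 5.0, "Strongly agree"),
)


@dataclass(frozen=True)
class LikertItemSummary:
    statement: str
    ratings: tuple[int, ...]
    mean: float
    sd: float
    interpretation: str


def likert_summary(
    statement: str,
    ratings: Sequence[int],
    bands: Sequence[tuple[float, float, str]] = DEFAULT_LIKERT_BANDS,
) -> LikertItemSummary:
    """Mean, sample SD (n-1), and interpretation label for one 1-5 item."""
    values = list(ratings)
    if len(values) < 2:
        raise EvaluationError("need at least 2 ratings for a sample SD")
    for r in values:
        if int(r) != r or not 1 <= r <= 5:
            raise EvaluationError(f"rating {r!r} outside the 1-5 integer scale")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    label = "Unclassified"
    for lo, hi, text in bands:
        # closed upper bound on the last band so a mean of exactly 5 lands
        if lo <= mean < hi or (mean == hi and hi == bands[-1][1]):
            label = text
            break
    return LikertItemSummary(
        statement=statement,
        ratings=tuple(int(r) for r in values),
        mean=mean,
        sd=sd,
        interpretation=label,
    )


# ---------------------------------------------------------------------------
# Whole-study report


@dataclass(frozen=True)
class ScenarioErrorTally:
    scenario_id: str
    n_trials: int
    n_correct_status: int
    n_trials_with_incorrect: int
    n_trials_with_missed: int
    total_correct: int
    total_incorrect: int
    total_missed: int


@dataclass(frozen=True)
class ScenarioTiming:
    scenario_id: str
    n_pairs: int
    mean_mmapp_s: float
    mean_comparator_s: float
    t: float | None
    df: int | None
    p: float | None


@dataclass(frozen=True)
class StudyReport:
    n_trials: int
    counts: ConfusionCounts
    sensitivity_pct: float | None  # None when no positive-truth trials
    specificity_pct: float | None  # None when no negative-truth trials
    n_correct_status: int
    pct_correct_status: float
    per_scenario: tuple[ScenarioErrorTally, ...]
    total_trials_with_incorrect: int
    total_trials_with_missed: int
    timing: tuple[ScenarioTiming, ...] = ()
    likert: tuple[LikertItemSummary, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "confusion": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            },
            "sensitivity_pct": (
                None if self.sensitivity_pct is None else round(self.sensitivity_pct, 1)
            ),
            "specificity_pct": (
                None if self.specificity_pct is None else round(self.specificity_pct, 1)
            ),
            "n_correct_status": self.n_correct_status,
            "pct_correct_status": round(self.pct_correct_status, 1),
            "per_scenario": [
                {
                    "scenario_id": s.scenario_id,
                    "n_trials": s.n_trials,
                    "n_correct_status": s.n_correct_status,
                    "n_trials_with_incorrect": s.n_trials_with_incorrect,
                    "n_trials_with_missed": s.n_trials_with_missed,
                    "total_correct": s.total_correct,
                    "total_incorrect": s.total_incorrect,
                    "total_missed": s.total_missed,
                }
                for s in self.per_scenario
            ],
            "total_trials_with_incorrect": self.total_trials_with_incorrect,
            "total_trials_with_missed": self.total_trials_with_missed,
            "timing": [
                {
                    "scenario_id": t.scenario_id,
                    "n_pairs": t.n_pairs,
                    "mean_mmapp_s": round(t.mean_mmapp_s, 1),
                    "mean_comparator_s": round(t.mean_comparator_s, 1),
                    "t": None if t.t is None else round(t.t, 3),
                    "df": t.df,
                    "p": None if t.p is None else round(t.p, 4),
                }
                for t in self.timing
            ],
            "likert": [
                {
                    "statement": item.statement,
                    "n": len(item.ratings),
                    "mean": round(item.mean, 2),
                    "sd": round(item.sd, 2),
                    "interpretation": item.interpretation,
                }
                for item in self.likert
            ],
        }


def evaluate_study(
    trials: Sequence[TrialRecord],
    surveys: Mapping[str, Sequence[int]] | None = None,
    likert_bands: Sequence[tuple[float, float, str]] = DEFAULT_LIKERT_BANDS,
) -> StudyReport:
    """Assemble the full feasibility report from trial records and surveys.

    Deterministic given its inputs; scenario sections follow first-appearance
    order of ``scenario_id``. Timing comparisons are computed per scenario on
    the trials carrying both completion times (paired within participant) and
    are skipped with null statistics when fewer than two pairs exist or the
    differences are degenerate.
    """
    if not trials:
        raise EvaluationError("no trials to evaluate")

    counts = confusion_counts(trials)
    n_correct = sum(
        1 for t in trials if t.predicted_multimorbid == t.truth_multimorbid
    )

    order: list[str] = []
    by_scenario: dict[str, list[TrialRecord]] = {}
    for trial in trials:
        if trial.scenario_id not in by_scenario:
            order.append(trial.scenario_id)
            by_scenario[trial.scenario_id] = []
        by_scenario[trial.scenario_id].append(trial)

    tallies: list[ScenarioErrorTally] = []
    timing: list[ScenarioTiming] = []
    for sid in order:
        group = by_scenario[sid]
        errors = [classify_selection_errors(t) for t in group]
        tallies.append(
            ScenarioErrorTally(
                scenario_id=sid,
                n_trials=len(group),
                n_correct_status=sum(
                    1 for t in group if t.predicted_multimorbid == t.truth_multimorbid
                ),
                n_trials_with_incorrect=sum(1 for _, inc, _ in errors if inc > 0),
                n_trials_with_missed=sum(1 for _, _, mis in errors if mis > 0),
                total_correct=sum(c for c, _, _ in errors),
                total_incorrect=sum(inc for _, inc, _ in errors),
                total_missed=sum(mis for _, _, mis in errors),
            )
        )
        timed = [
            t
            for t in group
            if t.mmapp_time_s is not None and t.comparator_time_s is not None
        ]
        if timed:
            a = [t.mmapp_time_s for t in timed]
            b = [t.comparator_time_s for t in timed]
            t_stat = df = p = None
            if len(timed) >= 2:
                try:
                    res = paired_t_test(a, b)
                    t_stat, df, p = res.t, res.df, res.p
                except DegenerateTestError:
                    pass
            timing.append(
                ScenarioTiming(
                    scenario_id=sid,
                    n_pairs=len(timed),
                    mean_mmapp_s=float(np.mean(a)),
                    mean_comparator_s=float(np.mean(b)),
                    t=t_stat,
                    df=df,
                    p=p,
                )
            )

    likert_items = tuple(
        likert_summary(statement, ratings, likert_bands)
        for statement, ratings in (surveys or {}).items()
    )

    try:
        sens = sensitivity(counts)
    except UndefinedMetricError:
        sens = None
    try:
        spec = specificity(counts)
    except UndefinedMetricError:
        spec = None

    return StudyReport(
        n_trials=len(trials),
        counts=counts,
        sensitivity_pct=sens,
        specificity_pct=spec,
        n_correct_status=n_correct,
        pct_correct_status=100.0 * n_correct / len(trials),
        per_scenario=tuple(tallies),
        total_trials_with_incorrect=sum(t.n_trials_with_incorrect for t in tallies),
        total_trials_with_missed=sum(t.n_trials_with_missed for t in tallies),
        timing=tuple(timing),
        likert=likert_items,
    )
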