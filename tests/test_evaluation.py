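import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import t as t_dist

from qcs.evaluation import (
    ConfusionCounts,
    DegenerateTestError,
    EvaluationError,
    TrialRecord,
    UndefinedMetricError,
    classify_selection_errors,
    confusion_counts,
    evaluate_study,
    likert_summary,
    paired_t_test,
    sensitivity,
    specificity,
)
from qcs.fixtures import builtin_trial_records


def _trial(selected, intended, truth=True, predicted=True, **kw):
    return TrialRecord(
        participant_id="P01",
        scenario_id="A",
        selected=frozenset(selected),
        intended=frozenset(intended),
        truth_multimorbid=truth,
        predicted_multimorbid=predicted,
        **kw,
    )


class TestClassifySelectionErrors:
    def test_perfect_selection(self):
        assert classify_selection_errors(_trial({"x", "y"}, {"x", "y"})) == (2, 0, 0)

    def test_one_incorrect_extra(self):
        # the published scenario-A behavior: both intended picked plus one extra
        trial = _trial(
            {"cardiac_arrhythmia", "c2", "endocrine_metabolic_disorder"},
            {"cardiac_arrhythmia", "c2"},
        )
        assert classify_selection_errors(trial) == (2, 1, 0)

    def test_one_missed(self):
        # published scenario-B behavior: one intended condition not selected
        intended = {"protein_calorie_malnutrition", "depression", "chronic_lung_disease", "c4"}
        trial = _trial(intended - {"protein_calorie_malnutrition"}, intended)
        assert classify_selection_errors(trial) == (3, 0, 1)

    @given(
        st.frozensets(st.sampled_from("abcdefgh"), max_size=8),
        st.frozensets(st.sampled_from("abcdefgh"), max_size=8),
    )
    def test_count_conservation(self, selected, intended):
        correct, incorrect, missed = classify_selection_errors(_trial(selected, intended))
        assert correct + missed == len(intended)
        assert correct + incorrect == len(selected)


class TestConfusionCounts:
    def test_empty(self):
        counts = confusion_counts([])
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (0, 0, 0, 0)

    def test_single_true_positive(self):
        counts = confusion_counts([_trial({}, {}, truth=True, predicted=True)])
        assert counts.tp == 1 and counts.total == 1

    def test_reference_fifty_trial_fixture(self):
        # frozen by arithmetic over the published per-scenario tallies:
        # correct counts (9,9,10,10,10), truths (No,Yes,Yes,No,Yes)
        counts = confusion_counts(builtin_trial_records())
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (29, 1, 19, 1)

    def test_missing_label_names_trial(self):
        bad = _trial({}, {}, truth=None, predicted=True)
        with pytest.raises(EvaluationError, match="P01/A"):
            confusion_counts([bad])

    def test_negative_time_rejected(self):
        with pytest.raises(EvaluationError, match="nonnegative"):
            _trial({}, {}, mmapp_time_s=-1.0)


class TestSensitivitySpecificity:
    def test_published_sensitivity(self):
        assert round(sensitivity(ConfusionCounts(tp=29, fp=0, tn=0, fn=1)), 1) == 96.7

    def test_published_specificity(self):
        assert round(specificity(ConfusionCounts(tp=0, fp=1, tn=19, fn=0)), 1) == 95.0

    def test_fifty_percent(self):
        assert sensitivity(ConfusionCounts(tp=10, fp=0, tn=0, fn=10)) == 50.0

    def test_zero_denominator_is_error_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(tp=0, fp=1, tn=1, fn=0))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(tp=1, fp=0, tn=0, fn=1))

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1))
    def test_range_and_reordering_invariance(self, labels):
        trials = [
            _trial({}, {}, truth=t, predicted=p) for t, p in labels
        ]
        counts = confusion_counts(trials)
        shuffled = confusion_counts(list(reversed(trials)))
        assert counts == shuffled
        if counts.tp + counts.fn > 0:
            assert 0.0 <= sensitivity(counts) <= 100.0
        if counts.tn + counts.fp > 0:
            assert 0.0 <= specificity(counts) <= 100.0


class TestPairedT:
    def test_symmetric_differences_t_zero(self):
        result = paired_t_test([1, 2, 3], [3, 2, 1])
        assert result.t == pytest.approx(0.0)
        assert result.p == pytest.approx(1.0)

    def test_against_textbook_formula_oracle(self):
        # frozen from the independent hand-formula computation:
        # d=[1,1,2,1], mean=1.25, s=0.5, t = 1.25/(0.5/2) = 5.0, df=3
        result = paired_t_test([10, 12, 14, 16], [9, 11, 12, 15])
        assert result.t == pytest.approx(5.0)
        assert result.df == 3
        assert result.p == pytest.approx(0.015392438073302294, rel=1e-9)

    def test_degenerate_differences(self):
        with pytest.raises(DegenerateTestError):
            paired_t_test([5, 5], [5, 5])
        with pytest.raises(DegenerateTestError):
            paired_t_test([6, 7], [5, 6])  # constant nonzero difference

    def test_unequal_lengths_rejected(self):
        with pytest.raises(EvaluationError, match="equal length"):
            paired_t_test([1, 2, 3], [1, 2])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(EvaluationError, match="at least 2"):
            paired_t_test([1], [2])

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
            ),
            min_size=3,
            max_size=20,
        )
    )
    def test_antisymmetry(self, pairs):
        a = [x for x, _ in pairs]
        b = [y for _, y in pairs]
        try:
            forward = paired_t_test(a, b)
        except DegenerateTestError:
            return
        backward = paired_t_test(b, a)
        assert forward.t == pytest.approx(-backward.t)
        assert forward.p == pytest.approx(backward.p)

    def test_oracle_formula_agreement_random(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 15))
            a = rng.normal(60, 10, n)
            b = a + rng.normal(1, 5, n)
            d = a - b
            sd = d.std(ddof=1)
            if sd < 1e-12:
                continue
            t_hand = d.mean() / (sd / math.sqrt(n))
            p_hand = 2 * t_dist.sf(abs(t_hand), n - 1)
            result = paired_t_test(a, b)
            assert result.t == pytest.approx(t_hand, rel=1e-10)
            assert result.p == pytest.approx(p_hand, rel=1e-10)


class TestLikertSummary:
    def test_published_easy_to_use_row(self):
        # {5 x8, 4 x2} is the unique ten-integer 1-5 multiset with mean 4.8
        # whose sample SD rounds to 0.42
        summary = likert_summary("It was easy to use", [5] * 8 + [4] * 2)
        assert summary.mean == pytest.approx(4.8)
        assert round(summary.sd, 2) == 0.42
        assert summary.interpretation == "Strongly agree"

    def test_population_sd_would_disagree(self):
        # the same multiset under a population (n) denominator rounds to 0.40,
        # confirming the sample-SD convention
        ratings = np.asarray([5] * 8 + [4] * 2, dtype=float)
        assert round(float(ratings.std(ddof=0)), 2) == 0.40

    def test_constant_ratings(self):
        summary = likert_summary("s", [3] * 10)
        assert summary.mean == 3.0 and summary.sd == 0.0
        assert summary.interpretation == "Neutral"

    def test_out_of_range_rejected(self):
        with pytest.raises(EvaluationError, match="outside"):
            likert_summary("s", [5, 6])
        with pytest.raises(EvaluationError, match="outside"):
            likert_summary("s", [0, 3])

    def test_custom_banding(self):
        bands = [(1.0, 5.0, "Whatever")]
        assert likert_summary("s", [1, 5], bands).interpretation == "Whatever"

    @given(st.lists(st.integers(1, 5), min_size=2, max_size=30))
    def test_sample_sd_matches_two_pass_formula(self, ratings):
        summary = likert_summary("s", ratings)
        n = len(ratings)
        mean = sum(ratings) / n
        var = sum((r - mean) ** 2 for r in ratings) / (n - 1)
        assert summary.sd == pytest.approx(math.sqrt(var))
        assert 1.0 <= summary.mean <= 5.0
        assert summary.sd >= 0.0


class TestEvaluateStudy:
    def test_empty_trials_rejected(self):
        with pytest.raises(EvaluationError, match="no trials"):
            evaluate_study([])

    def test_reference_fixture_headline_numbers(self):
        report = evaluate_study(builtin_trial_records())
        assert report.n_trials == 50
        assert round(report.sensitivity_pct, 1) == 96.7
        assert round(report.specificity_pct, 1) == 95.0
        assert report.n_correct_status == 48
        assert report.total_trials_with_incorrect == 3

    def test_scenario_means_match_hand_means(self):
        trials = [
            TrialRecord("P1", "A", frozenset(), frozenset(), True, True, 10.0, 20.0),
            TrialRecord("P2", "A", frozenset(), frozenset(), True, True, 30.0, 10.0),
            TrialRecord("P3", "A", frozenset(), frozenset(), True, True, 20.0, 30.0),
        ]
        report = evaluate_study(trials)
        timing = report.timing[0]
        assert timing.mean_mmapp_s == pytest.approx((10 + 30 + 20) / 3)
        assert timing.mean_comparator_s == pytest.approx(20.0)
        assert timing.n_pairs == 3

    def test_deterministic(self):
        trials = builtin_trial_records()
        assert evaluate_study(trials).to_dict() == evaluate_study(trials).to_dict()

    def test_survey_section(self):
        report = evaluate_study(
            builtin_trial_records(), surveys={"easy": [5] * 8 + [4] * 2}
        )
        assert report.likert[0].interpretation == "Strongly agree"
        assert report.to_dict()["likert"][0]["sd"] == 0.42
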