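"""Primary-outcome scoring, exact binomial inference, sample size."""

import math

import numpy as np
import pytest

from bcscreen import (
    SurveyResponse,
    ValidationError,
    attitude_score,
    exact_binomial_ci,
    likert_summary,
    outcomes_summary,
    sample_size_for_proportion,
)
from bcscreen.outcomes import (
    attitude_positivity,
    intention_to_participate,
    round_half_up,
)


class TestAttitudeScore:
    @pytest.mark.parametrize(
        "items,score,positive",
        [
            ((5, 5, 5), 15, True),
            ((4, 4, 4), 12, True),  # boundary: >= 12 counts as positive
            ((4, 4, 3), 11, False),
            ((1, 1, 1), 3, False),
        ],
    )
    def test_sum_and_threshold(self, items, score, positive):
        assert attitude_score(items) == (score, positive)

    def test_missing_item_undefined(self):
        with pytest.raises(ValidationError, match="missing"):
            attitude_score((5, None, 5))

    def test_cohort_positivity_counts_only_defined_scores(self):
        responses = [
            SurveyResponse("w1", (4, 4, 4)),
            SurveyResponse("w2", (5, 5, 5)),
            SurveyResponse("w3", (1, 1, 1)),
            SurveyResponse("w4", (5, None, 5)),  # excluded from denominator
        ]
        stats = attitude_positivity(responses)
        assert stats["n"] == 3
        assert stats["positive"] == 2


class TestExactBinomialCI:
    def test_zero_successes_lower_bound_zero(self):
        lo, hi = exact_binomial_ci(0, 25)
        assert lo == 0.0
        assert hi < 100.0

    def test_all_successes_upper_bound_hundred(self):
        lo, hi = exact_binomial_ci(25, 25)
        assert hi == 100.0
        assert lo > 0.0

    def test_printed_trial_intervals(self):
        lo, hi = exact_binomial_ci(205, 327)
        assert (round_half_up(lo), round_half_up(hi)) == (57.2, 67.9)
        lo, hi = exact_binomial_ci(299, 326)
        assert (round_half_up(lo), round_half_up(hi)) == (88.2, 94.5)

    def test_contains_point_estimate_and_shrinks_with_n(self):
        lo, hi = exact_binomial_ci(30, 100)
        assert lo < 30.0 < hi
        lo2, hi2 = exact_binomial_ci(300, 1000)
        assert hi2 - lo2 < hi - lo

    def test_zero_trials_rejected(self):
        with pytest.raises(ValidationError):
            exact_binomial_ci(0, 0)

    def test_agrees_with_tail_probability_search_oracle(self):
        """Clopper-Pearson bounds equal the direct inversion of the exact
        binomial tails, checked by bisection for a sweep of (s, n), n <= 50."""

        def tail_ge(p, n, s, comb):  # P(X >= s)
            k = np.arange(s, n + 1)
            return float(np.sum(comb[k] * p**k * (1 - p) ** (n - k)))

        def tail_le(p, n, s, comb):  # P(X <= s)
            k = np.arange(0, s + 1)
            return float(np.sum(comb[k] * p**k * (1 - p) ** (n - k)))

        def bisect(f, target, lo, hi, increasing):
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if (f(mid) < target) == increasing:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        alpha = 0.05
        for n in (1, 7, 23, 50):
            comb = np.array([math.comb(n, k) for k in range(n + 1)], dtype=float)
            for s in range(n + 1):
                lo, hi = exact_binomial_ci(s, n)
                if s == 0:
                    expect_lo = 0.0
                else:
                    expect_lo = bisect(
                        lambda p: tail_ge(p, n, s, comb), alpha / 2, 0.0, 1.0, True
                    )
                if s == n:
                    expect_hi = 1.0
                else:
                    expect_hi = bisect(
                        lambda p: tail_le(p, n, s, comb), alpha / 2, 0.0, 1.0, False
                    )
                assert lo / 100.0 == pytest.approx(expect_lo, abs=1e-6)
                assert hi / 100.0 == pytest.approx(expect_hi, abs=1e-6)


class TestSampleSize:
    def test_study_planning_value(self):
        assert sample_size_for_proportion(0.05, 0.95, 0.5) == 385

    def test_wider_interval_needs_fewer_women(self):
        assert sample_size_for_proportion(0.10, 0.95, 0.5) == 97

    def test_halving_width_roughly_quadruples_n(self):
        n1 = sample_size_for_proportion(0.04, 0.95, 0.5)
        n2 = sample_size_for_proportion(0.02, 0.95, 0.5)
        assert n2 / n1 == pytest.approx(4.0, rel=0.01)


class TestLikertSummary:
    def test_unanimous_responses(self):
        responses = [SurveyResponse(f"w{i}", (5, 5, 5), 1, 5) for i in range(10)]
        s = likert_summary(responses, "satisfaction")
        assert s["median"] == 5
        assert s["counts"][5] == 10
        assert all(s["counts"][lvl] == 0 for lvl in (1, 2, 3, 4))

    def test_trial_satisfaction_block(self):
        counts = {1: 1, 2: 0, 3: 9, 4: 38, 5: 298}
        responses = [
            SurveyResponse(f"w{i}_{lvl}", (None,) * 3, None, lvl)
            for lvl, c in counts.items()
            for i in range(c)
        ]
        s = likert_summary(responses, "satisfaction")
        assert s["n"] == 346
        pct = s["percentages"]
        assert (pct[1], pct[2], pct[3], pct[4], pct[5]) == (0.3, 0.0, 2.6, 11.0, 86.1)

    def test_median_matches_sort_based_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.integers(1, 6, size=101)
        responses = [
            SurveyResponse(f"w{i}", (None,) * 3, int(v), None)
            for i, v in enumerate(values)
        ]
        s = likert_summary(responses, "intention")
        assert s["median"] == float(sorted(values)[50])

    def test_unknown_item_rejected(self):
        with pytest.raises(ValidationError, match="unknown item"):
            likert_summary([], "happiness")

    def test_missing_values_excluded_from_denominator(self):
        responses = [
            SurveyResponse("w1", (None,) * 3, 1, None),
            SurveyResponse("w2", (None,) * 3, None, None),
        ]
        assert likert_summary(responses, "intention")["n"] == 1


def test_intention_dichotomization():
    responses = [
        SurveyResponse("w1", (None,) * 3, 1, None),  # definitely will
        SurveyResponse("w2", (None,) * 3, 2, None),  # likely
        SurveyResponse("w3", (None,) * 3, 3, None),
        SurveyResponse("w4", (None,) * 3, 5, None),
    ]
    stats = intention_to_participate(responses)
    assert stats["n"] == 4
    assert stats["intending"] == 2
    assert stats["proportion_pct"] == 50.0


def test_outcomes_summary_reports_per_block_denominators():
    responses = [
        SurveyResponse("w1", (4, 4, 4), 1, 5),
        SurveyResponse("w2", (5, None, 5), 2, None),
    ]
    summary = outcomes_summary(responses)
    assert summary["positive_attitude"]["n"] == 1
    assert summary["intention"]["n"] == 2
    assert summary["satisfaction"]["n"] == 1
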