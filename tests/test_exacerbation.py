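import datetime
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copdloop.exacerbation import (
    confirm_episode,
    daily_symptom_score,
    detect_episodes,
    exacerbation_summary,
    score_stream,
)
from copdloop.models import ALL_SYMPTOMS, MAJOR_SYMPTOMS, MINOR_SYMPTOMS

from conftest import D, make_entry, make_score, naive_detect


class TestDailyScore:
    def test_no_symptoms_scores_zero(self):
        s = daily_symptom_score(make_entry("P1", D(2020, 1, 1)))
        assert s.score == 0 and not s.flagged

    def test_all_symptoms_scores_19(self):
        s = daily_symptom_score(
            make_entry("P1", D(2020, 1, 1), **{k: True for k in ALL_SYMPTOMS}))
        assert (s.major_count, s.minor_count, s.score) == (3, 4, 19)

    def test_minor_only_not_flagged(self):
        s = daily_symptom_score(make_entry("P1", D(2020, 1, 1), cough=True, wheeze=True))
        assert s.score == 2 and not s.flagged

    def test_threshold_is_strict(self):
        # one major + one minor = 6: at the threshold, not above it
        s = daily_symptom_score(make_entry("P1", D(2020, 1, 1), dyspnea=True, cough=True))
        assert s.score == 6 and not s.flagged

    def test_enumeration_of_all_combinations(self):
        """Brute force over all 2^7 symptom vectors: scores stay in 0..19 and
        exactly 97 of 128 combinations exceed the threshold."""
        flagged = 0
        for bits in itertools.product([False, True], repeat=7):
            entry = make_entry("P1", D(2020, 1, 1), **dict(zip(ALL_SYMPTOMS, bits)))
            s = daily_symptom_score(entry)
            expected = 5 * sum(bits[:3]) + sum(bits[3:])  # weights applied by hand
            assert s.score == expected and 0 <= s.score <= 19
            flagged += s.flagged
        assert flagged == 97


class TestDetection:
    def test_two_consecutive_days_above_threshold(self):
        scores = [make_score("P1", D(2020, 1, 1), 7), make_score("P1", D(2020, 1, 2), 7)]
        (ep,) = detect_episodes(scores)
        assert (ep.start_date, ep.end_date, ep.peak_score) == (D(2020, 1, 1), D(2020, 1, 2), 7)
        assert ep.duration_days == 2

    def test_single_high_day_is_not_an_episode(self):
        scores = [make_score("P1", D(2020, 1, 1), 0),
                  make_score("P1", D(2020, 1, 2), 19),
                  make_score("P1", D(2020, 1, 3), 0)]
        assert detect_episodes(scores) == []

    def test_missing_day_breaks_a_run_by_default(self):
        scores = [make_score("P1", D(2020, 1, 1), 8), make_score("P1", D(2020, 1, 3), 8)]
        assert detect_episodes(scores) == []

    def test_gap_tolerant_policy_bridges_one_missing_day(self):
        scores = [make_score("P1", D(2020, 1, 1), 8), make_score("P1", D(2020, 1, 3), 8)]
        (ep,) = detect_episodes(scores, gap_tolerance=1)
        assert (ep.start_date, ep.end_date) == (D(2020, 1, 1), D(2020, 1, 3))

    def test_recorded_low_day_breaks_even_with_gap_tolerance(self):
        scores = [make_score("P1", D(2020, 1, 1), 8),
                  make_score("P1", D(2020, 1, 2), 0),
                  make_score("P1", D(2020, 1, 3), 8)]
        assert detect_episodes(scores, gap_tolerance=1) == []

    def test_two_runs_separated_by_low_day_stay_distinct(self):
        scores = [make_score("P1", D(2020, 1, d), s)
                  for d, s in [(1, 8), (2, 8), (3, 2), (4, 9), (5, 9)]]
        eps = detect_episodes(scores)
        assert [(e.start_date.day, e.end_date.day) for e in eps] == [(1, 2), (4, 5)]

    def test_unsorted_stream_rejected(self):
        scores = [make_score("P1", D(2020, 1, 2), 8), make_score("P1", D(2020, 1, 1), 8)]
        with pytest.raises(ValueError, match="sorted"):
            detect_episodes(scores)

    def test_episode_maximality(self):
        """Extending a detected episode one day in either direction always
        breaks a rule: the day is unrecorded or not flagged."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            days = sorted(rng.choice(40, size=25, replace=False))
            scores = [make_score("P1", D(2020, 1, 1) + datetime.timedelta(int(d)),
                                 int(rng.integers(0, 20))) for d in days]
            recorded = {s.date: s for s in scores}
            for ep in detect_episodes(scores):
                for edge in (ep.start_date - datetime.timedelta(1),
                             ep.end_date + datetime.timedelta(1)):
                    s = recorded.get(edge)
                    assert s is None or not s.flagged

    @given(st.lists(st.tuples(st.integers(0, 45), st.integers(0, 19)),
                    min_size=0, max_size=30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_naive_rescan_oracle(self, pairs):
        by_day = {}
        for day, score in pairs:  # last write wins: one score per date
            by_day[day] = score
        scores = [make_score("P1", D(2020, 1, 1) + datetime.timedelta(d), s)
                  for d, s in sorted(by_day.items())]
        assert detect_episodes(scores) == naive_detect(scores)


class TestConfirmation:
    def _episode(self):
        return detect_episodes([make_score("P1", D(2020, 1, 1), 8),
                                make_score("P1", D(2020, 1, 2), 8)])[0]

    def test_confirm_transition(self):
        ep = confirm_episode(self._episode(), "confirm")
        assert ep.status == "confirmed" and ep.decided_at is not None

    def test_reject_keeps_data_and_reason(self):
        ep = confirm_episode(self._episode(), "reject",
                             reason="worsening caused by cardiovascular disease")
        assert ep.status == "rejected"
        assert "cardiovascular" in ep.rejection_reason
        assert ep.day_scores == (8, 8)

    def test_double_decision_rejected(self):
        confirmed = confirm_episode(self._episode(), "confirm")
        with pytest.raises(ValueError, match="already confirmed"):
            confirm_episode(confirmed, "reject", reason="x")

    def test_rejection_needs_a_reason(self):
        with pytest.raises(ValueError, match="reason"):
            confirm_episode(self._episode(), "reject")


class TestSummary:
    def test_no_episodes_all_zero(self):
        s = exacerbation_summary([], ["P1", "P2"])
        assert s.per_patient_confirmed == {"P1": 0, "P2": 0}
        assert s.median == 0.0 and s.total_confirmed == 0

    def test_confirmed_by_subtraction_matches_direct_count(self):
        """117 suspected episodes with 7 rejected leave 110 confirmed."""
        eps = []
        for i in range(117):
            ep = detect_episodes([make_score(f"P{i % 39}", D(2020, 1, 1), 8),
                                  make_score(f"P{i % 39}", D(2020, 1, 2), 8)])[0]
            eps.append(confirm_episode(ep, "reject", reason="cardiovascular")
                       if i < 7 else confirm_episode(ep, "confirm"))
        s = exacerbation_summary(eps, [f"P{i}" for i in range(39)])
        assert s.total_suspected == 117 and s.total_rejected == 7
        assert s.total_confirmed == 117 - 7 == 110
        assert sum(s.per_patient_confirmed.values()) == 110

    def test_median_of_counts(self):
        eps = []
        for pid, n in [("P1", 1), ("P2", 2), ("P3", 6)]:
            for k in range(n):
                ep = detect_episodes([
                    make_score(pid, D(2020, 1, 1 + 3 * k), 8),
                    make_score(pid, D(2020, 1, 2 + 3 * k), 8)])[0]
                eps.append(confirm_episode(ep, "confirm"))
        s = exacerbation_summary(eps, ["P1", "P2", "P3"])
        assert s.median == 2.0
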