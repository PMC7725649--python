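import datetime
import math

import pytest

from copdloop.assessment import LungFunctionAssessment
from copdloop.exacerbation import detect_episodes
from copdloop.monitoring import (
    STREAMS,
    compliance,
    compliance_quartiles,
    generate_warnings,
    month_windows,
    monthly_compliance,
    overall_compliance,
    prescribed_counts,
    schedule_followups,
)
from copdloop.models import Cohort, PEFRecord, QuestionnaireResponse

from conftest import D, ENROLL, make_profile, make_score


class TestPrescription:
    def test_one_month_default(self):
        counts = prescribed_counts(1)
        assert counts == {s: 2 for s in STREAMS}
        assert sum(counts.values()) == 8

    def test_six_months(self):
        assert prescribed_counts(6) == {s: 12 for s in STREAMS}

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError):
            prescribed_counts(0)

    def test_month_windows_are_contiguous_and_closed(self):
        windows = month_windows(D(2017, 10, 1), 6)
        assert windows[0] == (D(2017, 10, 1), D(2017, 10, 31))
        for (_, end), (start, _) in zip(windows, windows[1:]):
            assert (start - end).days == 1


class TestCompliance:
    def test_full_compliance(self):
        rep = compliance({s: 2 for s in STREAMS}, prescribed_counts(1))
        assert rep.pooled_pct == 100.0

    def test_over_recording_capped_at_100(self):
        rep = compliance({"PEF": 3, "CAT": 2, "PHQ9": 2, "GAD7": 2}, prescribed_counts(1))
        assert rep.streams["PEF"].raw_ratio_pct == 150.0
        assert rep.streams["PEF"].capped_ratio_pct == 100.0
        assert rep.pooled_pct == 100.0

    def test_half_compliance(self):
        rep = compliance({"PEF": 1, "CAT": 1, "PHQ9": 1, "GAD7": 1}, prescribed_counts(1))
        assert rep.streams["PEF"].capped_ratio_pct == 50.0
        assert rep.pooled_pct == 50.0

    def test_capping_idempotence(self):
        actual = {"PEF": 5, "CAT": 1, "PHQ9": 0, "GAD7": 2}
        presc = prescribed_counts(1)
        once = compliance(actual, presc)
        capped_actual = {s: min(actual[s], presc[s]) for s in STREAMS}
        twice = compliance(capped_actual, presc)
        assert once.pooled_pct == twice.pooled_pct
        for s in STREAMS:
            assert once.streams[s].capped_ratio_pct == twice.streams[s].capped_ratio_pct

    def test_negative_actual_rejected(self):
        with pytest.raises(ValueError):
            compliance({"PEF": -1}, {"PEF": 2})

    def test_zero_prescription_rejected(self):
        with pytest.raises(ValueError):
            compliance({"PEF": 1}, {"PEF": 0})

    def test_monthly_counts_from_streams(self):
        cohort = Cohort(
            patients={"P1": make_profile("P1")},
            pef={"P1": [PEFRecord(patient_id="P1", date=D(2017, 10, 5), attempts=(300,)),
                        PEFRecord(patient_id="P1", date=D(2017, 10, 20), attempts=(310,))]},
            questionnaires={"P1": [QuestionnaireResponse(
                patient_id="P1", date=D(2017, 10, 5), instrument="CAT",
                items=(1,) * 8)]},
        )
        month1, month2 = monthly_compliance(cohort, "P1", 2)
        assert month1.streams["PEF"].actual == 2
        assert month1.pooled_pct == pytest.approx(100 * 3 / 8)
        assert month2.pooled_pct == 0.0
        overall = overall_compliance(cohort, "P1", 2)
        assert overall.pooled_pct == pytest.approx(100 * 3 / 16)


class TestQuartiles:
    def test_uniform_cohort(self):
        q = compliance_quartiles({f"P{i}": [100.0] * 3 for i in range(5)})
        assert all(m.median == 100.0 and m.q3 - m.q1 == 0.0 for m in q)

    def test_hand_computed_median(self):
        q = compliance_quartiles({
            "P1": [40.0], "P2": [60.0], "P3": [80.0], "P4": [100.0]})
        assert q[0].median == 70.0

    def test_dropout_zeros_pull_lower_quartile_to_zero(self):
        monthly = {f"C{i}": [100.0, 100.0] for i in range(2)}
        monthly.update({f"D{i}": [100.0, 0.0] for i in range(2)})
        q = compliance_quartiles(monthly)
        assert q[1].q1 == 0.0 and q[0].q1 == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            compliance_quartiles({})


def _episode(pid="P1", day=5):
    return detect_episodes([make_score(pid, D(2020, 1, day), 8),
                            make_score(pid, D(2020, 1, day + 1), 8)])[0]


class TestWarnings:
    def test_null_case_no_warnings(self):
        rep = compliance({s: 2 for s in STREAMS}, prescribed_counts(1), "P1",
                         (D(2020, 1, 1), D(2020, 1, 31)))
        assessment = LungFunctionAssessment(
            patient_id="P1", date=D(2020, 1, 1), gold_stage=2, pef_best=400,
            pef_predicted=450, pef_pct_pred=88.9, low_pef_flag=False)
        assert generate_warnings([assessment], [], [rep]) == []

    def test_one_warning_per_suspected_episode(self):
        warnings = generate_warnings(episodes=[_episode()])
        (w,) = warnings
        assert w.kind == "suspected_exacerbation" and w.date == D(2020, 1, 5)

    def test_low_compliance_threshold(self):
        rep = compliance({"PEF": 1, "CAT": 1, "PHQ9": 1, "GAD7": 0},  # pooled 37.5%
                         prescribed_counts(1), "P1", (D(2020, 1, 1), D(2020, 1, 31)))
        kinds = {w.kind for w in generate_warnings(compliance_reports=[rep])}
        assert "low_compliance" in kinds
        assert "missed_upload" in kinds  # GAD7 silent all month

    def test_low_pef_warning(self):
        a = LungFunctionAssessment(
            patient_id="P1", date=D(2020, 1, 1), gold_stage=3, pef_best=300,
            pef_predicted=500, pef_pct_pred=60.0, low_pef_flag=True)
        (w,) = generate_warnings(assessments=[a])
        assert w.kind == "low_pef" and w.payload_dict()["pef_pct_pred"] == 60.0

    def test_idempotent_under_duplicated_inputs(self):
        ep = _episode()
        once = generate_warnings(episodes=[ep])
        twice = generate_warnings(episodes=[ep, ep])
        assert once == twice


class TestScheduler:
    def test_182_day_horizon_gives_13_routine_events(self):
        sched = schedule_followups("P1", ENROLL, 182, interval_days=14)
        assert len(sched.routine) == 13
        days = [(e.due_date - ENROLL).days for e in sched.routine]
        assert days == list(range(14, 183, 14))
        assert sched.extra == []

    def test_each_warning_adds_exactly_one_extra(self):
        warnings = generate_warnings(episodes=[_episode("P1", 5), _episode("P1", 10)])
        sched = schedule_followups("P1", D(2020, 1, 1), 60, warnings)
        assert len(sched.extra) == len(warnings) == 2
        assert len(sched.routine) == 60 // 14

    def test_extra_due_next_day_and_linked(self):
        (w,) = generate_warnings(episodes=[_episode("P1", 20)])
        sched = schedule_followups("P1", D(2020, 1, 1), 60, [w])
        (extra,) = sched.extra
        assert extra.due_date == w.date + datetime.timedelta(days=1)
        assert extra.trigger == w

    def test_zero_horizon_keeps_warning_extras(self):
        (w,) = generate_warnings(episodes=[_episode()])
        sched = schedule_followups("P1", D(2020, 1, 1), 0, [w])
        assert sched.routine == [] and len(sched.extra) == 1

    def test_handled_warnings_do_not_schedule(self):
        (w,) = generate_warnings(episodes=[_episode()])
        from dataclasses import replace
        sched = schedule_followups("P1", D(2020, 1, 1), 60, [replace(w, handled=True)])
        assert sched.extra == []

    def test_schedule_density_bound(self):
        """Events in any window never exceed ceil(window/interval) + warnings
        falling in the window."""
        warnings = generate_warnings(episodes=[_episode("P1", d) for d in (3, 9, 20)])
        sched = schedule_followups("P1", D(2020, 1, 1), 90, warnings)
        for start_off in range(0, 80, 7):
            lo = D(2020, 1, 1) + datetime.timedelta(days=start_off)
            hi = lo + datetime.timedelta(days=21)
            n_events = sum(lo <= e.due_date <= hi for e in sched.events)
            n_warn = sum(lo <= w.date + datetime.timedelta(days=1) <= hi
                         for w in warnings)
            assert n_events <= math.ceil(22 / 14) + n_warn
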