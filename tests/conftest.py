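import datetime

import pytest

from copdloop.exacerbation import (
    SCORE_THRESHOLD,
    DailySymptomScore,
    ExacerbationEpisode,
)
from copdloop.models import (
    Cohort,
    PatientProfile,
    PEFRecord,
    QuestionnaireResponse,
    SymptomDiaryEntry,
)

D = datetime.date
ENROLL = D(2017, 10, 1)


def make_profile(pid="P1", **kw):
    defaults = dict(
        patient_id=pid, age=62, sex="male", height_cm=170.0,
        smoking_status="ex", fev1_pct_pred=55.0, fev1_fvc=60.0,
        enrollment_date=ENROLL,
    )
    defaults.update(kw)
    return PatientProfile(**defaults)


def make_entry(pid, date, **symptoms):
    return SymptomDiaryEntry(patient_id=pid, date=date, **symptoms)


def make_score(pid, date, score):
    """A DailySymptomScore with the requested total (majors first)."""
    major = min(score // 5, 3)
    minor = score - 5 * major
    assert 0 <= minor <= 4, f"score {score} not representable"
    return DailySymptomScore(patient_id=pid, date=date,
                             major_count=major, minor_count=minor, score=score)


def naive_detect(scores):
    """Independent day-by-day re-scan oracle for episode detection.

    Walks the full calendar range; a run accumulates only while every day is
    recorded and flagged, and closes on any other day.  Runs of >= 2 days
    become episodes.
    """
    if not scores:
        return []
    by_date = {s.date: s for s in scores}
    first, last = min(by_date), max(by_date)
    episodes, run = [], []
    day = first
    while day <= last + datetime.timedelta(days=1):
        s = by_date.get(day)
        if s is not None and s.score > SCORE_THRESHOLD:
            run.append(s)
        else:
            if len(run) >= 2:
                episodes.append(ExacerbationEpisode(
                    patient_id=run[0].patient_id,
                    start_date=run[0].date, end_date=run[-1].date,
                    day_scores=tuple(x.score for x in run),
                    peak_score=max(x.score for x in run),
                ))
            run = []
        day += datetime.timedelta(days=1)
    return episodes


@pytest.fixture
def small_cohort():
    """Three patients, handmade streams, two full months of data."""
    patients = {f"P{i}": make_profile(f"P{i}") for i in (1, 2, 3)}
    symptoms = {
        "P1": [
            make_entry("P1", D(2017, 10, 5), dyspnea=True, sputum_volume=True),
            make_entry("P1", D(2017, 10, 6), dyspnea=True, sputum_purulence=True,
                       cough=True),
            make_entry("P1", D(2017, 10, 7), cough=True),
        ],
        "P2": [make_entry("P2", D(2017, 10, 10), cough=True, wheeze=True)],
    }
    pef = {
        "P1": [PEFRecord(patient_id="P1", date=D(2017, 10, 1), attempts=(320, 340, 335)),
               PEFRecord(patient_id="P1", date=D(2017, 11, 12), attempts=(300,))],
        "P2": [PEFRecord(patient_id="P2", date=D(2017, 10, 2), attempts=(250, 260))],
    }
    questionnaires = {
        "P1": [
            QuestionnaireResponse(patient_id="P1", date=D(2017, 10, 1),
                                  instrument="CAT", items=(3, 2, 2, 2, 2, 2, 2, 2)),
            QuestionnaireResponse(patient_id="P1", date=D(2017, 11, 26),
                                  instrument="CAT", items=(2, 2, 2, 2, 2, 2, 1, 1)),
        ],
    }
    return Cohort(patients=patients, symptoms=symptoms, pef=pef,
                  questionnaires=questionnaires)
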