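"""Symptom-diary scoring and detection of suspected acute exacerbations.

Each diary day is scored as a weighted symptom sum: the three major
symptoms (dyspnea, sputum purulence, sputum volume) count 5 points each,
the four minor symptoms (nasal discharge or congestion, sore throat,
cough, wheeze) count 1 point each, so the daily score lies in 0..19.
A day flags when the score is strictly above 6, and a suspected
exacerbation is any maximal run of calendar-consecutive recorded flagged
days of length >= 2.  By default a missing diary day breaks a run (no
interpolation); a gap-tolerant policy that lets a run bridge up to
``gap_tolerance`` unrecorded days is available for sensitivity analysis.
A recorded non-flagged day always breaks a run.  Every suspected episode
then needs clinician confirmation before it enters outcome counts.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .models import MAJOR_SYMPTOMS, MINOR_SYMPTOMS, SymptomDiaryEntry

MAJOR_WEIGHT = 5
MINOR_WEIGHT = 1
SCORE_THRESHOLD = 6          # a day flags when score > 6, never at 6
MIN_CONSECUTIVE_DAYS = 2

SUSPECTED = "suspected"
CONFIRMED = "confirmed"
REJECTED = "rejected"


@dataclass(frozen=True)
class DailySymptomScore:
    patient_id: str
    date: datetime.date
    major_count: int
    minor_count: int
    score: int

    @property
    def flagged(self) -> bool:
        return self.score > SCORE_THRESHOLD


@dataclass(frozen=True)
class ExacerbationEpisode:
    patient_id: str
    start_date: datetime.date
    end_date: datetime.date
    day_scores: tuple[int, ...]
    peak_score: int
    status: str = SUSPECTED
    rejection_reason: str | None = None
    decided_at: datetime.datetime | None = None

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


def daily_symptom_score(entry: SymptomDiaryEntry) -> DailySymptomScore:
    """Weighted symptom sum for one diary day (majors x5, minors x1)."""
    major = sum(getattr(entry, s) for s in MAJOR_SYMPTOMS)
    minor = sum(getattr(entry, s) for s in MINOR_SYMPTOMS)
    return DailySymptomScore(
        patient_id=entry.patient_id,
        date=entry.date,
        major_count=major,
        minor_count=minor,
        score=MAJOR_WEIGHT * major + MINOR_WEIGHT * minor,
    )


def score_stream(entries: Iterable[SymptomDiaryEntry]) -> list[DailySymptomScore]:
    return [daily_symptom_score(e) for e in entries]


def detect_episodes(
    scores: Sequence[DailySymptomScore],
    gap_tolerance: int = 0,
    min_days: int = MIN_CONSECUTIVE_DAYS,
) -> list[ExacerbationEpisode]:
    """Find all suspected exacerbations in one patient's scored diary.

    The stream must be date-sorted with one score per recorded date.
    ``gap_tolerance`` unrecorded days may be bridged inside a run (default
    0: a missing day terminates it).  Episodes are disjoint and maximal;
    their day_scores hold only the recorded flagged days.
    """
    for prev, cur in zip(scores, scores[1:]):
        if cur.date <= prev.date:
            raise ValueError(
                f"score stream not strictly sorted by date at {cur.date}"
            )
        if cur.patient_id != prev.patient_id:
            raise ValueError("detect_episodes expects a single patient's stream")

    recorded = {s.date for s in scores}
    episodes: list[ExacerbationEpisode] = []
    run: list[DailySymptomScore] = []

    def close_run() -> None:
        if len(run) >= min_days:
            day_scores = tuple(s.score for s in run)
            episodes.append(ExacerbationEpisode(
                patient_id=run[0].patient_id,
                start_date=run[0].date,
                end_date=run[-1].date,
                day_scores=day_scores,
                peak_score=max(day_scores),
            ))
        run.clear()

    for s in scores:
        if not s.flagged:
            close_run()
            continue
        if run:
            gap = (s.date - run[-1].date).days - 1  # unrecorded days in between
            bridgeable = gap <= gap_tolerance and not any(
                run[-1].date + datetime.timedelta(days=k) in recorded
                for k in range(1, gap + 1)
            )
            if not bridgeable:
                close_run()
        run.append(s)
    close_run()
    return episodes


def detect_cohort_episodes(
    symptoms: dict[str, list[SymptomDiaryEntry]],
    gap_tolerance: int = 0,
) -> list[ExacerbationEpisode]:
    """Run detection over every patient's diary stream."""
    out: list[ExacerbationEpisode] = []
    for pid in sorted(symptoms):
        out.extend(detect_episodes(score_stream(symptoms[pid]), gap_tolerance))
    return out


def confirm_episode(
    episode: ExacerbationEpisode,
    decision: str,
    reason: str | None = None,
    when: datetime.datetime | None = None,
) -> ExacerbationEpisode:
    """Record the clinician's decision on a suspected episode.

    Rejected episodes keep their data and carry the stated reason (for
    example, symptom worsening caused by cardiovascular disease); deciding
    a non-suspected episode again is an error.
    """
    if episode.status != SUSPECTED:
        raise ValueError(
            f"episode already {episode.status}; only suspected episodes can be decided"
        )
    if decision not in (CONFIRMED, REJECTED, "confirm", "reject"):
        raise ValueError(f"decision must be 'confirm' or 'reject', got {decision!r}")
    status = CONFIRMED if decision in (CONFIRMED, "confirm") else REJECTED
    if status == REJECTED and not reason:
        raise ValueError("a rejection needs a reason")
    return replace(episode, status=status, rejection_reason=reason,
                   decided_at=when or datetime.datetime.now())


@dataclass(frozen=True)
class ExacerbationSummary:
    per_patient_confirmed: dict[str, int]
    total_suspected: int
    total_confirmed: int
    total_rejected: int
    median: float
    q1: float
    q3: float


def exacerbation_summary(
    episodes: Sequence[ExacerbationEpisode],
    patient_ids: Iterable[str],
) -> ExacerbationSummary:
    """Per-patient confirmed-episode counts plus the cohort median and IQR.

    Patients without any episode contribute a zero count; only confirmed
    episodes are counted.
    """
    counts = {pid: 0 for pid in patient_ids}
    n_confirmed = n_rejected = n_suspected = 0
    for ep in episodes:
        if ep.status == CONFIRMED:
            n_confirmed += 1
            counts[ep.patient_id] = counts.get(ep.patient_id, 0) + 1
        elif ep.status == REJECTED:
            n_rejected += 1
        else:
            n_suspected += 1
    values = np.array(sorted(counts.values()), dtype=float)
    if values.size == 0:
        med = q1 = q3 = 0.0
    else:
        q1, med, q3 = np.percentile(values, [25, 50, 75])
    return ExacerbationSummary(
        per_patient_confirmed=counts,
        total_suspected=n_suspected + n_confirmed + n_rejected,
        total_confirmed=n_confirmed,
        total_rejected=n_rejected,
        median=float(med), q1=float(q1), q3=float(q3),
    )
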