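"""Compliance computation, warning generation and follow-up scheduling.

Compliance is the ratio of actually uploaded self-monitoring records to
the prescribed number, capped at 100 %: patients who record more often
than prescribed count as fully compliant, never more.  The prescription
defaults to 2 records per stream (PEF, CAT, PHQ-9, GAD-7) per calendar
month — the biweekly logging plan — and compliance is reported per month
and pooled over a period.  Warnings fire on suspected exacerbations, low
PEF, low monthly compliance and silent streams; routine follow-up runs
every 14 days from enrollment, and every unhandled warning schedules
exactly one extra follow-up the next day.  All rules are pure functions of
records plus configuration, so re-running the engine is idempotent.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import DEFAULT_CONFIG
from .exacerbation import ExacerbationEpisode

STREAMS = ("PEF", "CAT", "PHQ9", "GAD7")

SUSPECTED_EXACERBATION = "suspected_exacerbation"
LOW_PEF = "low_pef"
LOW_COMPLIANCE = "low_compliance"
MISSED_UPLOAD = "missed_upload"


@dataclass(frozen=True)
class StreamCompliance:
    prescribed: int
    actual: int

    @property
    def raw_ratio_pct(self) -> float:
        return 100.0 * self.actual / self.prescribed

    @property
    def capped_ratio_pct(self) -> float:
        return min(self.raw_ratio_pct, 100.0)


@dataclass(frozen=True)
class ComplianceReport:
    patient_id: str
    period_start: datetime.date
    period_end: datetime.date
    streams: dict[str, StreamCompliance]

    @property
    def pooled_pct(self) -> float:
        """Pooled capped ratio: sum of capped actuals over sum prescribed."""
        prescribed = sum(s.prescribed for s in self.streams.values())
        capped_actual = sum(min(s.actual, s.prescribed) for s in self.streams.values())
        return 100.0 * capped_actual / prescribed


@dataclass(frozen=True)
class Warning:
    patient_id: str
    date: datetime.date
    kind: str
    payload: tuple[tuple[str, object], ...] = ()
    handled: bool = False

    def payload_dict(self) -> dict:
        return dict(self.payload)


@dataclass(frozen=True)
class FollowUpEvent:
    patient_id: str
    due_date: datetime.date
    kind: str                     # "routine" | "extra"
    trigger: Warning | None = None
    completed: bool = False


@dataclass(frozen=True)
class FollowUpSchedule:
    patient_id: str
    events: tuple[FollowUpEvent, ...]

    @property
    def routine(self) -> list[FollowUpEvent]:
        return [e for e in self.events if e.kind == "routine"]

    @property
    def extra(self) -> list[FollowUpEvent]:
        return [e for e in self.events if e.kind == "extra"]


def month_windows(start: datetime.date, n_months: int) -> list[tuple[datetime.date, datetime.date]]:
    """Closed monthly windows from ``start``: window i covers
    [start + i months, start + (i+1) months - 1 day]."""
    import pandas as pd

    if n_months < 1:
        raise ValueError("a period must span at least one month")
    ts = pd.Timestamp(start)
    edges = [(ts + pd.DateOffset(months=i)).date() for i in range(n_months + 1)]
    return [
        (edges[i], edges[i + 1] - datetime.timedelta(days=1))
        for i in range(n_months)
    ]


def prescribed_counts(
    n_months: int,
    frequency: Mapping | None = None,
) -> dict[str, int]:
    """Expected record counts per stream over ``n_months`` calendar months.

    Default prescription is 2 per stream per month (biweekly logging); the
    pooled prescription is the sum over streams.
    """
    if n_months < 1:
        raise ValueError("a prescription period must span at least one month")
    cfg = frequency or DEFAULT_CONFIG["monitoring"]
    per_month = cfg["records_per_stream_per_month"]
    return {s: per_month * n_months for s in cfg["streams"]}


def compliance(
    actual: Mapping[str, int],
    prescribed: Mapping[str, int],
    patient_id: str = "",
    period: tuple[datetime.date, datetime.date] | None = None,
) -> ComplianceReport:
    """Per-stream and pooled compliance, each ratio capped at 100 %."""
    streams = {}
    for name, presc in prescribed.items():
        if presc <= 0:
            raise ValueError(f"prescribed count for {name} must be positive")
        act = actual.get(name, 0)
        if act < 0:
            raise ValueError(f"actual count for {name} must be non-negative")
        streams[name] = StreamCompliance(prescribed=presc, actual=act)
    start, end = period or (datetime.date.min, datetime.date.max)
    return ComplianceReport(patient_id=patient_id, period_start=start,
                            period_end=end, streams=streams)


def _count_in_window(dates: Sequence[datetime.date],
                     window: tuple[datetime.date, datetime.date]) -> int:
    lo, hi = window
    return sum(1 for d in dates if lo <= d <= hi)


def stream_dates(cohort, patient_id: str) -> dict[str, list[datetime.date]]:
    """Upload dates per monitored stream for one patient."""
    dates: dict[str, list[datetime.date]] = {s: [] for s in STREAMS}
    for r in cohort.pef.get(patient_id, []):
        dates["PEF"].append(r.date)
    for q in cohort.questionnaires.get(patient_id, []):
        dates[q.instrument.value].append(q.date)
    return dates


def monthly_compliance(
    cohort,
    patient_id: str,
    n_months: int,
    frequency: Mapping | None = None,
) -> list[ComplianceReport]:
    """One compliance report per calendar month from the patient's enrollment."""
    enrollment = cohort.patients[patient_id].enrollment_date
    cfg = frequency or DEFAULT_CONFIG["monitoring"]
    per_month = prescribed_counts(1, cfg)
    dates = stream_dates(cohort, patient_id)
    reports = []
    for window in month_windows(enrollment, n_months):
        actual = {s: _count_in_window(dates[s], window) for s in per_month}
        reports.append(compliance(actual, per_month, patient_id, window))
    return reports


def overall_compliance(
    cohort, patient_id: str, n_months: int, frequency: Mapping | None = None
) -> ComplianceReport:
    """Pooled compliance over the whole management horizon."""
    enrollment = cohort.patients[patient_id].enrollment_date
    presc = prescribed_counts(n_months, frequency)
    window = (enrollment, month_windows(enrollment, n_months)[-1][1])
    dates = stream_dates(cohort, patient_id)
    actual = {s: _count_in_window(dates[s], window) for s in presc}
    return compliance(actual, presc, patient_id, window)


@dataclass(frozen=True)
class MonthlyQuartiles:
    month: int            # 1-based month index
    q1: float
    median: float
    q3: float
    n: int


def compliance_quartiles(
    monthly_pct: Mapping[str, Sequence[float]],
) -> list[MonthlyQuartiles]:
    """Median and quartiles of monthly pooled compliance across a cohort.

    ``monthly_pct`` maps patient id to a per-month list of pooled
    percentages.  For the all-enrolled series the caller fills months after
    a patient's exit with 0 % (see :func:`cohort_monthly_matrix`); for the
    completer series only completers are passed in.
    """
    if not monthly_pct:
        raise ValueError("at least one patient is required")
    n_months = max(len(v) for v in monthly_pct.values())
    out = []
    for m in range(n_months):
        vals = np.array([v[m] for v in monthly_pct.values() if len(v) > m])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append(MonthlyQuartiles(month=m + 1, q1=float(q1), median=float(med),
                                    q3=float(q3), n=vals.size))
    return out


def cohort_monthly_matrix(
    cohort,
    n_months: int,
    dropout_month: Mapping[str, int] | None = None,
    completers_only: bool = False,
) -> dict[str, list[float]]:
    """Per-patient monthly pooled compliance, ready for quartile summaries.

    ``dropout_month`` gives the 1-based month in which a patient exited;
    months at or after exit count as 0 % in the all-enrolled series, and
    dropouts are excluded entirely when ``completers_only``.
    """
    dropout_month = dropout_month or {}
    out: dict[str, list[float]] = {}
    for pid in cohort.patient_ids:
        exit_m = dropout_month.get(pid)
        if completers_only and exit_m is not None:
            continue
        series = [r.pooled_pct for r in monthly_compliance(cohort, pid, n_months)]
        if exit_m is not None:
            series = [v if m + 1 < exit_m else 0.0 for m, v in enumerate(series)]
        out[pid] = series
    return out


def generate_warnings(
    assessments: Iterable = (),
    episodes: Iterable[ExacerbationEpisode] = (),
    compliance_reports: Iterable[ComplianceReport] = (),
    thresholds: Mapping | None = None,
) -> list[Warning]:
    """Derive the warning stream from one pass over the monitored data.

    Emitted kinds: ``suspected_exacerbation`` (exactly one per detected
    episode), ``low_pef`` (percent-predicted below threshold, default 80),
    ``low_compliance`` (monthly pooled ratio below threshold, default 50 %)
    and ``missed_upload`` (a stream with zero records in a prescription
    month).  Deterministic and idempotent: the same inputs always produce
    the same de-duplicated warning set.
    """
    mon = thresholds or DEFAULT_CONFIG["monitoring"]
    pef_thr = (thresholds or DEFAULT_CONFIG["pef"]).get(
        "low_pct_pred_threshold", DEFAULT_CONFIG["pef"]["low_pct_pred_threshold"])
    comp_thr = mon.get("low_compliance_threshold_pct",
                       DEFAULT_CONFIG["monitoring"]["low_compliance_threshold_pct"])

    seen: set[tuple] = set()
    warnings: list[Warning] = []

    def emit(w: Warning) -> None:
        key = (w.patient_id, w.kind, w.date, w.payload)
        if key not in seen:
            seen.add(key)
            warnings.append(w)

    for ep in episodes:
        emit(Warning(
            patient_id=ep.patient_id, date=ep.start_date, kind=SUSPECTED_EXACERBATION,
            payload=(("start", ep.start_date.isoformat()),
                     ("end", ep.end_date.isoformat()),
                     ("peak_score", ep.peak_score)),
        ))
    for a in assessments:
        if a.low_pef_flag:
            emit(Warning(
                patient_id=a.patient_id, date=a.date, kind=LOW_PEF,
                payload=(("pef_pct_pred", round(a.pef_pct_pred, 1)),),
            ))
    for rep in compliance_reports:
        if rep.pooled_pct < comp_thr:
            emit(Warning(
                patient_id=rep.patient_id, date=rep.period_end, kind=LOW_COMPLIANCE,
                payload=(("pooled_pct", round(rep.pooled_pct, 1)),),
            ))
        for name, sc in rep.streams.items():
            if sc.actual == 0:
                emit(Warning(
                    patient_id=rep.patient_id, date=rep.period_end, kind=MISSED_UPLOAD,
                    payload=(("stream", name),),
                ))
    warnings.sort(key=lambda w: (w.patient_id, w.date, w.kind, w.payload))
    return warnings


def schedule_followups(
    patient_id: str,
    enrollment: datetime.date,
    horizon_days: int,
    warnings: Iterable[Warning] = (),
    interval_days: int | None = None,
    extra_offset_days: int | None = None,
) -> FollowUpSchedule:
    """Routine follow-ups every ``interval_days`` from enrollment plus one
    extra follow-up per unhandled warning.

    Routine contacts fall on enrollment + k*interval for k = 1..floor(
    horizon/interval); a horizon shorter than one interval yields no
    routine events but warnings still produce extras, due the day after
    the warning by default.  Extras never replace routine events.
    """
    mon = DEFAULT_CONFIG["monitoring"]
    interval = interval_days if interval_days is not None else mon["routine_followup_interval_days"]
    offset = extra_offset_days if extra_offset_days is not None else mon["extra_followup_offset_days"]
    if interval < 1:
        raise ValueError("the follow-up interval must be at least one day")
    if horizon_days < 0:
        raise ValueError("the horizon cannot be negative")

    events = [
        FollowUpEvent(patient_id=patient_id,
                      due_date=enrollment + datetime.timedelta(days=k * interval),
                      kind="routine")
        for k in range(1, horizon_days // interval + 1)
    ]
    for w in warnings:
        if not w.handled:
            events.append(FollowUpEvent(
                patient_id=patient_id,
                due_date=w.date + datetime.timedelta(days=offset),
                kind="extra", trigger=w,
            ))
    events.sort(key=lambda e: (e.due_date, e.kind))
    return FollowUpSchedule(patient_id=patient_id, events=tuple(events))
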