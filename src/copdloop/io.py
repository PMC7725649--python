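"""Reading and writing cohort record streams.

Two on-disk layouts carry the same five streams:

* ``delimited`` — a directory of UTF-8 CSV files with header rows
  (``patients.csv``, ``symptoms.csv``, ``pef.csv``, ``questionnaires.csv``,
  ``adverse_events.csv``);
* ``structured`` — one JSON file bundling the streams under their names.

Both layouts are described by the machine-readable schema shipped at
``copdloop/data/schemas.json`` (see :func:`schema`).  Loading validates
every row against the domain-type invariants, normalizes duplicates
(symptoms OR-merged, PEF sessions keep the higher best, questionnaires
keep the latest row) and sorts each per-patient stream by date.
Round-trip is stable: ``load_cohort(write_records(c, ...)) == c``.
"""
from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
from pydantic import ValidationError

from .models import (
    ALL_SYMPTOMS,
    AdverseEvent,
    Cohort,
    PatientProfile,
    PEFRecord,
    QuestionnaireResponse,
    SymptomDiaryEntry,
)

FORMATS = ("delimited", "structured")

STREAM_FILES = {
    "patients": "patients.csv",
    "symptoms": "symptoms.csv",
    "pef": "pef.csv",
    "questionnaires": "questionnaires.csv",
    "adverse_events": "adverse_events.csv",
}

#: header written when a stream has no records (optional columns omitted)
_EMPTY_HEADERS = {
    "patients": ["patient_id", "age", "sex", "smoking_status",
                 "fev1_pct_pred", "fev1_fvc", "enrollment_date"],
    "symptoms": ["patient_id", "date", *ALL_SYMPTOMS],
    "pef": ["patient_id", "date", "attempt1"],
    "questionnaires": ["patient_id", "date", "instrument",
                       *[f"item{i}" for i in range(1, 8)]],
    "adverse_events": ["patient_id", "date", "kind", "copd_related", "period"],
}

_TRUE = {"1", "true", "True", "TRUE", "yes"}
_FALSE = {"0", "false", "False", "FALSE", "no", ""}


class CohortValidationError(ValueError):
    """A row violated a stated invariant; carries file and row number."""


def schema() -> dict:
    """Return the machine-readable description of the on-disk schemas."""
    text = resources.files("copdloop.data").joinpath("schemas.json").read_text()
    return json.loads(text)


def _bool(raw: str, field: str) -> bool:
    if raw in _TRUE:
        return True
    if raw in _FALSE:
        return False
    raise ValueError(f"{field}: cannot interpret {raw!r} as a boolean")


def _opt(raw: str) -> str | None:
    return raw if raw not in ("", "nan") else None


def _rowerr(fname: str, idx: int, reason: str) -> CohortValidationError:
    # +2: header row plus 1-based numbering
    return CohortValidationError(f"{fname} row {idx + 2}: {reason}")


def _parse_patient(row: dict) -> PatientProfile:
    return PatientProfile(
        patient_id=row["patient_id"],
        age=int(row["age"]),
        sex=row["sex"],
        height_cm=float(row["height_cm"]) if _opt(row.get("height_cm", "")) else None,
        education=_opt(row.get("education", "")),
        smoking_status=row["smoking_status"],
        fev1_pct_pred=float(row["fev1_pct_pred"]),
        fev1_fvc=float(row["fev1_fvc"]),
        enrollment_date=row["enrollment_date"],
    )


def _parse_symptom(row: dict) -> SymptomDiaryEntry:
    return SymptomDiaryEntry(
        patient_id=row["patient_id"],
        date=row["date"],
        **{s: _bool(str(row[s]), s) for s in ALL_SYMPTOMS},
    )


def _parse_pef(row: dict) -> PEFRecord:
    attempts = tuple(
        float(row[c]) for c in ("attempt1", "attempt2", "attempt3")
        if _opt(str(row.get(c, "")))
    )
    return PEFRecord(patient_id=row["patient_id"], date=row["date"], attempts=attempts)


def _parse_questionnaire(row: dict) -> QuestionnaireResponse:
    items = tuple(
        int(float(row[c])) for c in (f"item{i}" for i in range(1, 10))
        if _opt(str(row.get(c, "")))
    )
    return QuestionnaireResponse(
        patient_id=row["patient_id"], date=row["date"],
        instrument=row["instrument"], items=items,
    )


def _parse_adverse(row: dict) -> AdverseEvent:
    return AdverseEvent(
        patient_id=row["patient_id"],
        date=row["date"],
        kind=row["kind"],
        copd_related=_bool(str(row["copd_related"]), "copd_related"),
        period=row["period"],
    )


_PARSERS = {
    "patients": _parse_patient,
    "symptoms": _parse_symptom,
    "pef": _parse_pef,
    "questionnaires": _parse_questionnaire,
    "adverse_events": _parse_adverse,
}


def _parse_rows(stream: str, rows: list[dict], source: str) -> list:
    parser = _PARSERS[stream]
    out = []
    for i, row in enumerate(rows):
        try:
            out.append(parser(row))
        except (ValidationError, ValueError, KeyError) as exc:
            reason = exc.errors()[0]["msg"] if isinstance(exc, ValidationError) else str(exc)
            raise _rowerr(source, i, reason) from exc
    return out


def _dedup_and_sort(cohort_rows: dict[str, list]) -> Cohort:
    patients: dict[str, PatientProfile] = {}
    for p in cohort_rows["patients"]:
        patients[p.patient_id] = p  # later profile rows win

    symptoms: dict[str, dict] = {}
    for e in cohort_rows["symptoms"]:
        key = symptoms.setdefault(e.patient_id, {})
        key[e.date] = key[e.date].merged_with(e) if e.date in key else e

    pef: dict[str, dict] = {}
    for r in cohort_rows["pef"]:
        key = pef.setdefault(r.patient_id, {})
        if r.date not in key or r.best > key[r.date].best:
            key[r.date] = r

    quest: dict[str, dict] = {}
    for q in cohort_rows["questionnaires"]:
        quest.setdefault(q.patient_id, {})[(q.date, q.instrument)] = q  # latest wins

    adverse: dict[str, list] = {}
    for a in cohort_rows["adverse_events"]:
        adverse.setdefault(a.patient_id, []).append(a)

    return Cohort(
        patients=patients,
        symptoms={k: sorted(v.values(), key=lambda e: e.date) for k, v in symptoms.items()},
        pef={k: sorted(v.values(), key=lambda r: r.date) for k, v in pef.items()},
        questionnaires={
            k: sorted(v.values(), key=lambda q: (q.date, q.instrument.value))
            for k, v in quest.items()
        },
        adverse_events={k: sorted(v, key=lambda a: a.date) for k, v in adverse.items()},
    )


def load_cohort(path: str | Path, format: str | None = None) -> Cohort:
    """Load a cohort from a CSV directory (``delimited``) or JSON file
    (``structured``); the format is inferred from the path when not given.
    """
    path = Path(path)
    if format is None:
        format = "structured" if path.suffix == ".json" else "delimited"
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; supported formats: {FORMATS}")

    raw: dict[str, list[dict]] = {}
    if format == "structured":
        bundle = json.loads(path.read_text())
        for stream in STREAM_FILES:
            raw[stream] = [
                {k: str(v) if v is not None else "" for k, v in row.items()}
                for row in bundle.get(stream, [])
            ]
        source = {s: path.name for s in STREAM_FILES}
    else:
        source = {}
        for stream, fname in STREAM_FILES.items():
            f = path / fname
            source[stream] = fname
            if not f.exists():
                raw[stream] = []
                continue
            try:
                df = pd.read_csv(f, dtype=str, keep_default_na=False)
            except pd.errors.EmptyDataError:
                df = pd.DataFrame()
            raw[stream] = df.to_dict("records")

    rows = {s: _parse_rows(s, raw[s], source[s]) for s in STREAM_FILES}
    return _dedup_and_sort(rows)


def _frames(cohort: Cohort) -> dict[str, pd.DataFrame]:
    pts = [
        {
            "patient_id": p.patient_id, "age": p.age, "sex": p.sex.value,
            "height_cm": p.height_cm, "education": p.education,
            "smoking_status": p.smoking_status.value,
            "fev1_pct_pred": p.fev1_pct_pred, "fev1_fvc": p.fev1_fvc,
            "enrollment_date": p.enrollment_date.isoformat(),
        }
        for _, p in sorted(cohort.patients.items())
    ]
    sym = [
        {"patient_id": e.patient_id, "date": e.date.isoformat(),
         **{s: int(getattr(e, s)) for s in ALL_SYMPTOMS}}
        for pid in sorted(cohort.symptoms) for e in cohort.symptoms[pid]
    ]
    pef = [
        {"patient_id": r.patient_id, "date": r.date.isoformat(),
         **{f"attempt{i + 1}": (r.attempts[i] if i < len(r.attempts) else None)
            for i in range(3)}}
        for pid in sorted(cohort.pef) for r in cohort.pef[pid]
    ]
    quest = [
        {"patient_id": q.patient_id, "date": q.date.isoformat(),
         "instrument": q.instrument.value,
         **{f"item{i + 1}": (q.items[i] if i < len(q.items) else None)
            for i in range(9)}}
        for pid in sorted(cohort.questionnaires) for q in cohort.questionnaires[pid]
    ]
    adverse = [
        {"patient_id": a.patient_id, "date": a.date.isoformat(), "kind": a.kind.value,
         "copd_related": int(a.copd_related), "period": a.period.value}
        for pid in sorted(cohort.adverse_events) for a in cohort.adverse_events[pid]
    ]
    out = {}
    for stream, records in [("patients", pts), ("symptoms", sym), ("pef", pef),
                            ("questionnaires", quest), ("adverse_events", adverse)]:
        df = pd.DataFrame.from_records(records)
        # optional columns absent for every record are omitted from the file
        if len(df):
            df = df.dropna(axis="columns", how="all")
        else:
            df = pd.DataFrame(columns=_EMPTY_HEADERS[stream])
        out[stream] = df
    return out


def write_records(cohort: Cohort, path: str | Path, format: str = "delimited") -> Path:
    """Write a cohort to ``path``: a directory of CSVs (``delimited``) or a
    single JSON file (``structured``).  Returns the path written."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; supported formats: {FORMATS}")
    path = Path(path)
    frames = _frames(cohort)
    if format == "delimited":
        path.mkdir(parents=True, exist_ok=True)
        for stream, fname in STREAM_FILES.items():
            frames[stream].to_csv(path / fname, index=False)
    else:
        bundle = {
            stream: json.loads(frames[stream].to_json(orient="records"))
            for stream in STREAM_FILES
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(bundle, indent=1))
    return path
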