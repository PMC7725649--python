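"""Domain records shared by every stage of the management pathway.

All records are validated pydantic models.  Dates are ISO-8601 calendar
dates; every interval in the package is closed on both ends and measured
in whole days, because the symptom diary has one-day granularity.
"""
from __future__ import annotations

import datetime
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

MAJOR_SYMPTOMS = ("dyspnea", "sputum_purulence", "sputum_volume")
MINOR_SYMPTOMS = ("nasal_discharge_or_congestion", "sore_throat", "cough", "wheeze")
ALL_SYMPTOMS = MAJOR_SYMPTOMS + MINOR_SYMPTOMS

#: items, minimum item value, maximum item value — per instrument
INSTRUMENT_ITEM_SPEC = {
    "CAT": (8, 0, 5),
    "PHQ9": (9, 0, 3),
    "GAD7": (7, 0, 3),
}


class Sex(str, Enum):
    male = "male"
    female = "female"


class SmokingStatus(str, Enum):
    ex = "ex"
    current = "current"
    never = "never"


class Instrument(str, Enum):
    CAT = "CAT"
    PHQ9 = "PHQ9"
    GAD7 = "GAD7"


class AdverseEventKind(str, Enum):
    death = "death"
    hospitalization = "hospitalization"
    clinic_visit = "clinic_visit"


class StudyPeriod(str, Enum):
    pre_study = "pre_study"
    study = "study"


class PatientProfile(BaseModel):
    """Static attributes and baseline lung function of one participant."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    age: int
    sex: Sex
    height_cm: Optional[float] = Field(default=None, gt=0, lt=250)
    education: Optional[str] = None
    smoking_status: SmokingStatus = SmokingStatus.never
    fev1_pct_pred: float = Field(gt=0, le=200)
    fev1_fvc: float = Field(gt=0, le=100)
    enrollment_date: datetime.date

    @field_validator("age")
    @classmethod
    def _age_inclusion(cls, v: int) -> int:
        if v < 40:
            raise ValueError(
                f"age {v} violates the inclusion criterion age >= 40 years"
            )
        return v


class SymptomDiaryEntry(BaseModel):
    """One calendar day's seven boolean symptoms for one patient.

    Dyspnea, sputum purulence and sputum volume are the major symptoms;
    nasal discharge/congestion, sore throat, cough and wheeze are minor.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: datetime.date
    dyspnea: bool = False
    sputum_purulence: bool = False
    sputum_volume: bool = False
    nasal_discharge_or_congestion: bool = False
    sore_throat: bool = False
    cough: bool = False
    wheeze: bool = False

    def merged_with(self, other: "SymptomDiaryEntry") -> "SymptomDiaryEntry":
        """OR-merge duplicate same-day entries (conservative toward detection)."""
        if (other.patient_id, other.date) != (self.patient_id, self.date):
            raise ValueError("can only merge entries for the same patient and date")
        return SymptomDiaryEntry(
            patient_id=self.patient_id,
            date=self.date,
            **{s: getattr(self, s) or getattr(other, s) for s in ALL_SYMPTOMS},
        )


class PEFRecord(BaseModel):
    """One peak-expiratory-flow session: up to 3 attempts, best kept."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: datetime.date
    attempts: tuple[float, ...]

    @field_validator("attempts")
    @classmethod
    def _attempts_valid(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not 1 <= len(v) <= 3:
            raise ValueError("a PEF session records 1 to 3 attempts")
        for a in v:
            if not 0 < a <= 1000:
                raise ValueError(f"PEF attempt {a} L/min outside (0, 1000]")
        return v

    @property
    def best(self) -> float:
        """Highest of the repeated measurements — the value the pathway uses."""
        return max(self.attempts)


class QuestionnaireResponse(BaseModel):
    """Item-level response to one of the three instruments (CAT/PHQ-9/GAD-7)."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: datetime.date
    instrument: Instrument
    items: tuple[int, ...]

    @model_validator(mode="after")
    def _items_valid(self) -> "QuestionnaireResponse":
        n, lo, hi = INSTRUMENT_ITEM_SPEC[self.instrument.value]
        if len(self.items) != n:
            raise ValueError(
                f"{self.instrument.value} requires exactly {n} items, got {len(self.items)}"
            )
        for x in self.items:
            if not lo <= x <= hi:
                raise ValueError(
                    f"{self.instrument.value} item value {x} outside {lo}..{hi}"
                )
        return self

    @property
    def total(self) -> int:
        return sum(self.items)


class AdverseEvent(BaseModel):
    """A death, hospitalization or clinic visit; only COPD-related events
    enter outcome counts."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: datetime.date
    kind: AdverseEventKind
    copd_related: bool = True
    period: StudyPeriod = StudyPeriod.study


class Cohort(BaseModel):
    """All per-patient record streams, each sorted by date."""

    patients: dict[str, PatientProfile] = Field(default_factory=dict)
    symptoms: dict[str, list[SymptomDiaryEntry]] = Field(default_factory=dict)
    pef: dict[str, list[PEFRecord]] = Field(default_factory=dict)
    questionnaires: dict[str, list[QuestionnaireResponse]] = Field(default_factory=dict)
    adverse_events: dict[str, list[AdverseEvent]] = Field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.patients)

    def stream(self, name: str) -> dict:
        return getattr(self, name)
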