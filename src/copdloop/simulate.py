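"""Synthetic-cohort generator with known ground truth.

The generator emulates a 6-month remote-management cohort the way the
pathway's study population looks: mostly male ex-smokers in their sixties,
a GOLD stage mix of roughly 18/41/15/26 %, biweekly PEF and questionnaire
uploads thinned by a per-patient adherence probability, daily symptom
diaries with injected exacerbation episodes (about 2 per patient per 6
months, overdispersed, lasting ~4 days), a slow multiplicative PEF decline
with dips during episodes, questionnaire totals that drift by a
configurable improvement effect, and a monthly dropout hazard calibrated
so roughly 30 % of enrollees exit by month 6.

Everything stochastic flows from one seed, so identical configurations
produce byte-identical cohorts.  The ground truth (true episode intervals,
true adherence, dropout month) is returned alongside the records, which
makes detector-recovery and compliance-recovery tests possible without any
real patient data.  Within- and between-day symptom draws are independent
given episode state; real diaries are autocorrelated beyond that.
"""
from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .assessment import predicted_pef
from .models import (
    MAJOR_SYMPTOMS,
    MINOR_SYMPTOMS,
    AdverseEvent,
    Cohort,
    PatientProfile,
    PEFRecord,
    QuestionnaireResponse,
)
from .models import SymptomDiaryEntry
from .monitoring import month_windows

_ITEM_MAX = {"CAT": 5, "PHQ9": 3, "GAD7": 3}
_N_ITEMS = {"CAT": 8, "PHQ9": 9, "GAD7": 7}
_TOTAL_MAX = {"CAT": 40, "PHQ9": 27, "GAD7": 21}


class SimulationConfig(BaseModel):
    """All knobs of the synthetic cohort; defaults emulate the study conditions."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=56, ge=1)
    months: int = Field(default=6, ge=1)
    seed: int = 0
    start_date: datetime.date = datetime.date(2017, 10, 1)

    # demographics
    male_p: float = Field(default=36 / 39, ge=0, le=1)
    age_mean: float = 61.82
    age_sd: float = Field(default=6.09, ge=0)
    height_mean_male: float = 168.0
    height_mean_female: float = 156.0
    height_sd: float = Field(default=6.0, ge=0)
    gold_probs: tuple[float, float, float, float] = (7 / 39, 16 / 39, 6 / 39, 10 / 39)
    #: FEV1 %pred sampled uniformly inside the stage's spirometric band
    fev1_band_by_stage: dict[int, tuple[float, float]] = {
        1: (80.0, 95.0), 2: (50.0, 79.9), 3: (30.0, 49.9), 4: (15.0, 29.9),
    }

    # peak flow
    pef_pct_pred_by_stage: dict[int, float] = {1: 85.0, 2: 65.0, 3: 45.0, 4: 30.0}
    pef_pct_pred_sd: float = Field(default=8.0, ge=0)
    pef_monthly_decline_pct: float = Field(default=2.4, ge=0)
    pef_noise_log_sd: float = Field(default=0.04, ge=0)
    pef_episode_dip_pct: float = Field(default=15.0, ge=0, le=90)

    # exacerbation process
    exacerbation_mean_per_6mo: float = Field(default=2.0, ge=0)
    exacerbation_dispersion: float = Field(default=1.5, gt=0)   # negative-binomial k
    episode_mean_extra_days: float = Field(default=3.0, gt=0)   # duration = 1 + Geom
    p_flag_in_episode: float = Field(default=0.9, ge=0, le=1)
    p_major_out: float = Field(default=0.02, ge=0, le=1)
    p_minor_out: float = Field(default=0.08, ge=0, le=1)
    p_major_flagged: float = Field(default=0.8, ge=0, le=1)
    p_minor_flagged: float = Field(default=0.5, ge=0, le=1)

    # adherence (per-patient upload probability) and dropout
    adherence_alpha: float = Field(default=6.0, gt=0)
    adherence_beta: float = Field(default=0.8, gt=0)
    adherence_fixed: Optional[float] = Field(default=None, ge=0, le=1)
    dropout_hazard_per_month: float = Field(default=0.0577, ge=0, le=1)

    # questionnaires
    questionnaire_baseline: dict[str, float] = {"CAT": 17.0, "PHQ9": 6.0, "GAD7": 4.0}
    improvement_points: dict[str, float] = {"CAT": 3.0, "PHQ9": 2.0, "GAD7": 1.0}
    improvement_effect: float = 1.0        # 0 disables any systematic pre/post change
    severity_sd: float = Field(default=0.08, ge=0)

    # adverse events (per-patient Poisson means over the matching 6-month window)
    ae_pre_clinic_mean: float = Field(default=115 / 39, ge=0)
    ae_pre_hosp_mean: float = Field(default=69 / 39, ge=0)
    ae_study_clinic_mean: float = Field(default=52 / 39, ge=0)
    ae_study_hosp_mean: float = Field(default=19 / 39, ge=0)
    ae_death_p: float = Field(default=1 / 56, ge=0, le=1)
    ae_non_copd_mean: float = Field(default=0.3, ge=0)

    @model_validator(mode="after")
    def _valid(self) -> "SimulationConfig":
        if abs(sum(self.gold_probs) - 1.0) > 1e-9:
            raise ValueError("GOLD stage probabilities must sum to 1")
        return self


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""
    episodes: dict[str, list[tuple[datetime.date, datetime.date]]]
    adherence: dict[str, float]
    dropout_month: dict[str, Optional[int]]   # 1-based month of exit, None = completer
    latent: dict[str, dict] = field(default_factory=dict)

    def completers(self) -> list[str]:
        return sorted(p for p, m in self.dropout_month.items() if m is None)


def _horizon_days(cfg: SimulationConfig) -> int:
    last = month_windows(cfg.start_date, cfg.months)[-1][1]
    return (last - cfg.start_date).days + 1


def generate_cohort(cfg: SimulationConfig) -> tuple[list[PatientProfile], GroundTruth]:
    """Draw patient profiles and the per-patient ground truth.

    Reproducible: the same config (including seed) yields identical output.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    horizon = _horizon_days(cfg)
    profiles: list[PatientProfile] = []
    truth = GroundTruth(episodes={}, adherence={}, dropout_month={})

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:04d}"
        sex = "male" if rng.random() < cfg.male_p else "female"
        age = int(np.clip(round(rng.normal(cfg.age_mean, cfg.age_sd)), 40, 95))
        height = rng.normal(
            cfg.height_mean_male if sex == "male" else cfg.height_mean_female,
            cfg.height_sd,
        )
        stage = int(rng.choice(4, p=cfg.gold_probs)) + 1
        lo, hi = cfg.fev1_band_by_stage[stage]
        fev1 = rng.uniform(lo, hi)
        profiles.append(PatientProfile(
            patient_id=pid, age=age, sex=sex, height_cm=round(height, 1),
            education=rng.choice(
                ["primary_or_below", "secondary", "high_school", "college_or_above"],
                p=[5 / 39, 12 / 39, 16 / 39, 6 / 39]),
            smoking_status=rng.choice(["ex", "current", "never"],
                                      p=[30 / 39, 3 / 39, 6 / 39]),
            fev1_pct_pred=round(fev1, 1),
            fev1_fvc=round(float(np.clip(rng.normal(51.45, 13.97), 20, 95)), 1),
            enrollment_date=cfg.start_date,
        ))

        # adherence and dropout
        adherence = (cfg.adherence_fixed if cfg.adherence_fixed is not None
                     else float(rng.beta(cfg.adherence_alpha, cfg.adherence_beta)))
        truth.adherence[pid] = adherence
        dropout = None
        for m in range(1, cfg.months + 1):
            if rng.random() < cfg.dropout_hazard_per_month:
                dropout = m
                break
        truth.dropout_month[pid] = dropout

        # injected exacerbation episodes: overdispersed count, geometric length,
        # placed without overlap and with >= 2 quiet days between episodes so
        # neighbouring runs stay distinct
        mean_n = cfg.exacerbation_mean_per_6mo * cfg.months / 6.0
        k = cfg.exacerbation_dispersion
        n_epi = int(rng.negative_binomial(k, k / (k + mean_n))) if mean_n > 0 else 0
        intervals: list[tuple[int, int]] = []
        for _ in range(n_epi):
            dur = 1 + int(rng.geometric(1.0 / cfg.episode_mean_extra_days))
            dur = min(dur, horizon - 2)  # keep every episode inside the horizon
            for _attempt in range(50):
                s = int(rng.integers(1, max(2, horizon - dur)))
                e = s + dur - 1
                if all(e < a - 2 or s > b + 2 for a, b in intervals):
                    intervals.append((s, e))
                    break
        intervals.sort()
        truth.episodes[pid] = [
            (cfg.start_date + datetime.timedelta(days=s),
             cfg.start_date + datetime.timedelta(days=e))
            for s, e in intervals
        ]

        # latent trajectories reused by the stream simulator
        truth.latent[pid] = {
            "pef_pct0": float(np.clip(
                rng.normal(cfg.pef_pct_pred_by_stage[stage], cfg.pef_pct_pred_sd),
                10, 120)),
            "severity": {
                inst: float(np.clip(
                    cfg.questionnaire_baseline[inst] / _TOTAL_MAX[inst]
                    + rng.normal(0, cfg.severity_sd),
                    0.02, 0.95))
                for inst in ("CAT", "PHQ9", "GAD7")
            },
        }
    return profiles, truth


def _flagged_day(rng: np.random.Generator, cfg: SimulationConfig) -> dict[str, bool]:
    """Symptom vector guaranteed to score above the detection threshold."""
    majors = {s: bool(rng.random() < cfg.p_major_flagged) for s in MAJOR_SYMPTOMS}
    minors = {s: bool(rng.random() < cfg.p_minor_flagged) for s in MINOR_SYMPTOMS}
    score = 5 * sum(majors.values()) + sum(minors.values())
    if score <= 6:  # force two majors: 10 points
        majors["dyspnea"] = True
        majors["sputum_volume"] = True
    return {**majors, **minors}


def _quiet_day(rng: np.random.Generator, cfg: SimulationConfig) -> dict[str, bool]:
    return {
        **{s: bool(rng.random() < cfg.p_major_out) for s in MAJOR_SYMPTOMS},
        **{s: bool(rng.random() < cfg.p_minor_out) for s in MINOR_SYMPTOMS},
    }


def _questionnaire_items(
    rng: np.random.Generator, inst: str, p: float
) -> tuple[int, ...]:
    p = float(np.clip(p, 0.0, 1.0))
    return tuple(int(x) for x in rng.binomial(_ITEM_MAX[inst], p, size=_N_ITEMS[inst]))


def simulate_streams(
    profiles: list[PatientProfile],
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> Cohort:
    """Emit the five record streams for a generated cohort.

    Uploads (diary days, biweekly PEF sessions and questionnaires) are each
    thinned by the patient's true adherence probability; all streams stop at
    the dropout month.  Every emitted record passes the shared schema
    validation by construction.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    horizon = _horizon_days(cfg)
    windows = month_windows(cfg.start_date, cfg.months)

    cohort = Cohort(patients={p.patient_id: p for p in profiles})

    for profile in profiles:
        pid = profile.patient_id
        adherence = truth.adherence[pid]
        dropout = truth.dropout_month[pid]
        # a patient exiting in month m contributes nothing from that month on
        last_day = ((windows[dropout - 2][1] - cfg.start_date).days
                    if dropout and dropout > 1 else (-1 if dropout == 1 else horizon - 1))
        episode_days: set[int] = set()
        for s, e in truth.episodes[pid]:
            episode_days.update(range((s - cfg.start_date).days,
                                      (e - cfg.start_date).days + 1))

        # --- daily symptom diary ---
        entries = []
        for day in range(0, last_day + 1):
            in_episode = day in episode_days
            if in_episode and rng.random() < cfg.p_flag_in_episode:
                symptoms = _flagged_day(rng, cfg)
            else:
                symptoms = _quiet_day(rng, cfg)
            recorded = rng.random() < adherence
            if recorded:
                entries.append(SymptomDiaryEntry(
                    patient_id=pid,
                    date=cfg.start_date + datetime.timedelta(days=day),
                    **symptoms,
                ))
        if entries:
            cohort.symptoms[pid] = entries

        # --- biweekly PEF sessions and questionnaires ---
        predicted = predicted_pef(profile)
        pct0 = truth.latent[pid]["pef_pct0"]
        pef_records, quest_records = [], []
        # two upload slots per calendar month (the biweekly prescription):
        # the window's first day and 14 days later
        slot_days = [
            d for w_start, w_end in windows
            for d in ((w_start - cfg.start_date).days,
                      (w_start - cfg.start_date).days + 14)
            if d <= (w_end - cfg.start_date).days
        ]
        for day in slot_days:
            if day > last_day:
                continue
            date = cfg.start_date + datetime.timedelta(days=day)
            frac = day / max(horizon - 1, 1)
            if rng.random() < adherence:
                level = (predicted * pct0 / 100.0
                         * (1 - cfg.pef_monthly_decline_pct / 100.0) ** (day / 30.44))
                if day in episode_days:
                    level *= 1 - cfg.pef_episode_dip_pct / 100.0
                best = level * math.exp(rng.normal(0, cfg.pef_noise_log_sd))
                best = float(np.clip(best, 10, 1000))
                n_att = int(rng.integers(1, 4))
                attempts = [best] + [
                    max(best * (1 - rng.uniform(0, 0.06)), 5.0)
                    for _ in range(n_att - 1)
                ]
                pef_records.append(PEFRecord(
                    patient_id=pid, date=date,
                    attempts=tuple(round(a, 1) for a in attempts),
                ))
            for inst in ("CAT", "PHQ9", "GAD7"):
                if rng.random() < adherence:
                    drop = (cfg.improvement_effect * cfg.improvement_points[inst]
                            / _TOTAL_MAX[inst]) * frac
                    p = truth.latent[pid]["severity"][inst] - drop
                    quest_records.append(QuestionnaireResponse(
                        patient_id=pid, date=date, instrument=inst,
                        items=_questionnaire_items(rng, inst, p),
                    ))
        if pef_records:
            cohort.pef[pid] = pef_records
        if quest_records:
            # canonical stream order, matching the loader
            quest_records.sort(key=lambda q: (q.date, q.instrument.value))
            cohort.questionnaires[pid] = quest_records

        # --- adverse events (COPD-related, pre-study vs study, plus noise) ---
        events = []
        pre_lo = cfg.start_date - datetime.timedelta(days=horizon)
        observed_frac = (last_day + 1) / horizon if horizon else 0.0
        for kind, mean, period in (
            ("clinic_visit", cfg.ae_pre_clinic_mean, "pre_study"),
            ("hospitalization", cfg.ae_pre_hosp_mean, "pre_study"),
            ("clinic_visit", cfg.ae_study_clinic_mean * observed_frac, "study"),
            ("hospitalization", cfg.ae_study_hosp_mean * observed_frac, "study"),
        ):
            for _ in range(int(rng.poisson(mean))):
                offset = int(rng.integers(0, horizon))
                date = (pre_lo + datetime.timedelta(days=offset) if period == "pre_study"
                        else cfg.start_date + datetime.timedelta(days=min(offset, max(last_day, 0))))
                events.append(AdverseEvent(patient_id=pid, date=date, kind=kind,
                                           copd_related=True, period=period))
        for _ in range(int(rng.poisson(cfg.ae_non_copd_mean))):
            events.append(AdverseEvent(
                patient_id=pid,
                date=cfg.start_date + datetime.timedelta(days=int(rng.integers(0, max(last_day, 0) + 1))),
                kind="clinic_visit", copd_related=False, period="study"))
        if rng.random() < cfg.ae_death_p:
            events.append(AdverseEvent(
                patient_id=pid, date=cfg.start_date + datetime.timedelta(days=max(last_day, 0)),
                kind="death", copd_related=True, period="study"))
        if events:
            cohort.adverse_events[pid] = sorted(events, key=lambda a: a.date)

    return cohort


def simulate_cohort(cfg: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Generate profiles, ground truth and all five record streams."""
    profiles, truth = generate_cohort(cfg)
    return simulate_streams(profiles, truth, cfg), truth


def questionnaire_panel(
    cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Baseline and 6-month questionnaire totals for ``n_patients`` completers.

    Uses the same emission model as :func:`simulate_streams` (per-patient
    latent severity, binomial items, improvement drift), skipping the stream
    plumbing; intended for paired-test calibration at the study sample size.
    """
    out = {}
    for inst in ("CAT", "PHQ9", "GAD7"):
        base_p = cfg.questionnaire_baseline[inst] / _TOTAL_MAX[inst]
        latent = np.clip(
            base_p + rng.normal(0, cfg.severity_sd, size=cfg.n_patients), 0.02, 0.95)
        drop = cfg.improvement_effect * cfg.improvement_points[inst] / _TOTAL_MAX[inst]
        baseline = rng.binomial(_ITEM_MAX[inst], latent[:, None],
                                size=(cfg.n_patients, _N_ITEMS[inst])).sum(axis=1)
        post_p = np.clip(latent - drop, 0.0, 1.0)
        post = rng.binomial(_ITEM_MAX[inst], post_p[:, None],
                            size=(cfg.n_patients, _N_ITEMS[inst])).sum(axis=1)
        out[inst] = (baseline, post)
    return out


def detector_sensitivity(cohort: Cohort, truth: GroundTruth,
                         gap_tolerance: int = 0) -> float:
    """Fraction of true injected episodes (length >= 2 days) recovered by the
    symptom-score detector, i.e. overlapped by at least one detected episode."""
    from .exacerbation import detect_cohort_episodes

    detected = detect_cohort_episodes(cohort.symptoms, gap_tolerance)
    by_patient: dict[str, list] = {}
    for ep in detected:
        by_patient.setdefault(ep.patient_id, []).append(ep)

    total = recovered = 0
    for pid, intervals in truth.episodes.items():
        for s, e in intervals:
            if (e - s).days + 1 < 2:
                continue
            total += 1
            if any(d.start_date <= e and d.end_date >= s
                   for d in by_patient.get(pid, [])):
                recovered += 1
    return recovered / total if total else float("nan")
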