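"""Pulmonary-function evaluation and hierarchical risk classification.

Home monitoring in this pathway rests on the peak expiratory flow (PEF):
the best of up to three attempts on a hand-held meter, expressed as a
percentage of a demographic-predicted value.  A PEF strictly below 80 % of
predicted raises a low-PEF flag, and rising within-window PEF variability
is an early-warning index.  Spirometric GOLD staging (FEV1 % predicted at
cuts 80/50/30) feeds, together with the CAT score and event history, a
risk-by-symptom management grid that sets the follow-up cadence.

The PEF reference equation is pluggable.  The shipped default is the
Nunn & Gregg (1989, BMJ 298:1068-70) adult regression on ln(PEF in L/min)
by sex, age and height; any callable ``profile -> predicted L/min`` can be
registered instead, and an explicitly supplied predicted value always
bypasses the equation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from typing import Callable, Sequence

from .config import DEFAULT_CONFIG
from .models import PatientProfile, Sex


@dataclass(frozen=True)
class LungFunctionAssessment:
    patient_id: str
    date: Date | None
    gold_stage: int
    pef_best: float
    pef_predicted: float
    pef_pct_pred: float
    low_pef_flag: bool
    pef_variability: float | None = None


@dataclass(frozen=True, order=True)
class RiskLevel:
    """One cell of the management grid; higher level means tighter follow-up."""
    level: int
    label: str = ""
    followup_interval_days: int = 14
    records_per_stream_per_month: int = 2


def gold_stage(fev1_pct_pred: float, thresholds: Sequence[float] | None = None) -> int:
    """GOLD spirometric stage 1-4 from FEV1 % predicted (default cuts 80/50/30)."""
    if fev1_pct_pred <= 0:
        raise ValueError(f"FEV1 % predicted must be positive, got {fev1_pct_pred}")
    cuts = thresholds if thresholds is not None else DEFAULT_CONFIG["gold_thresholds"]
    for stage, cut in enumerate(cuts, start=1):
        if fev1_pct_pred >= cut:
            return stage
    return len(cuts) + 1


def best_of_three(attempts: Sequence[float]) -> float:
    """The highest of 1-3 repeated PEF measurements."""
    if not attempts:
        raise ValueError("no PEF attempts supplied")
    if not any(a > 0 for a in attempts):
        raise ValueError("at least one PEF attempt must be positive")
    return max(attempts)


def nunn_gregg_predicted_pef(profile: PatientProfile) -> float:
    """Predicted PEF (L/min) from the Nunn & Gregg adult regression.

    ln PEF = 0.544 ln(age) - 0.0151 age - 74.7/height + 5.48   (men)
    ln PEF = 0.376 ln(age) - 0.0120 age - 58.8/height + 5.63   (women)
    with height in cm.
    """
    if profile.height_cm is None:
        raise ValueError(
            f"patient {profile.patient_id}: the Nunn-Gregg equation needs height_cm"
        )
    a, h = profile.age, profile.height_cm
    if profile.sex is Sex.male:
        ln_pef = 0.544 * math.log(a) - 0.0151 * a - 74.7 / h + 5.48
    else:
        ln_pef = 0.376 * math.log(a) - 0.0120 * a - 58.8 / h + 5.63
    return math.exp(ln_pef)


REFERENCE_EQUATIONS: dict[str, Callable[[PatientProfile], float]] = {
    "nunn_gregg": nunn_gregg_predicted_pef,
}


def predicted_pef(profile: PatientProfile, equation: str = "nunn_gregg") -> float:
    try:
        return REFERENCE_EQUATIONS[equation](profile)
    except KeyError:
        raise ValueError(
            f"unknown PEF reference equation {equation!r}; "
            f"available: {sorted(REFERENCE_EQUATIONS)}"
        ) from None


def pef_percent_predicted(
    best: float,
    profile: PatientProfile | None = None,
    predicted: float | None = None,
    equation: str = "nunn_gregg",
    low_threshold: float | None = None,
) -> tuple[float, bool]:
    """PEF as % of predicted plus the low-PEF flag (strictly below threshold).

    ``predicted`` may be injected directly; otherwise it comes from the
    configured reference equation applied to ``profile``.
    """
    if predicted is None:
        if profile is None:
            raise ValueError("either a profile or an explicit predicted value is required")
        predicted = predicted_pef(profile, equation)
    if predicted <= 0:
        raise ValueError("predicted PEF must be positive")
    thr = low_threshold if low_threshold is not None else DEFAULT_CONFIG["pef"]["low_pct_pred_threshold"]
    pct = 100.0 * best / predicted
    return pct, pct < thr


def pef_variability(
    series: Sequence[tuple[Date, float]],
    window_days: int,
    metric: str = "amplitude_percent_mean",
    reference_date: Date | None = None,
) -> float:
    """PEF variability (%) over the trailing window ending at ``reference_date``
    (default: the last observation).

    ``amplitude_percent_mean`` is 100 x (max - min) / mean; ``cv`` is the
    coefficient of variation 100 x sd / mean (population sd).
    """
    if metric not in ("amplitude_percent_mean", "cv"):
        raise ValueError(f"unknown variability metric {metric!r}")
    if not series:
        raise ValueError("PEF variability is undefined for an empty series")
    ref = reference_date or max(d for d, _ in series)
    values = [v for d, v in series if 0 <= (ref - d).days <= window_days - 1]
    if len(values) < 2:
        raise ValueError(
            f"PEF variability needs at least 2 values in the {window_days}-day window, "
            f"got {len(values)}"
        )
    mean = sum(values) / len(values)
    if metric == "amplitude_percent_mean":
        return 100.0 * (max(values) - min(values)) / mean
    var = sum((v - mean) ** 2 for v in values) / len(values)
    return 100.0 * math.sqrt(var) / mean


def classify_risk(
    gold: int,
    cat_total: int,
    exacerbation_history: int,
    hospitalizations: int,
    rules: dict | None = None,
) -> RiskLevel:
    """Place a patient on the risk-by-symptom management grid.

    Default rule: high risk iff >= 2 exacerbations per 6 months, or >= 1
    hospitalization, or GOLD stage >= 3; symptomatic iff CAT >= 10.  The
    grid (and its follow-up intervals) is configuration data.
    """
    for name, v in (("gold", gold), ("cat_total", cat_total),
                    ("exacerbation_history", exacerbation_history),
                    ("hospitalizations", hospitalizations)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    rules = rules or DEFAULT_CONFIG["risk_rules"]
    hi = rules["high_risk_if"]
    high = (
        exacerbation_history >= hi["exacerbations_per_6mo"]
        or hospitalizations >= hi["hospitalizations"]
        or gold >= hi["gold_stage"]
    )
    symptomatic = cat_total >= rules["symptomatic_if_cat_at_least"]
    key = f"{'high_risk' if high else 'low_risk'},{'symptomatic' if symptomatic else 'low_symptom'}"
    cell = rules["levels"][key]
    return RiskLevel(
        level=cell["level"],
        label=cell["label"],
        followup_interval_days=cell["followup_interval_days"],
        records_per_stream_per_month=cell["records_per_stream_per_month"],
    )


def assess_patient(
    profile: PatientProfile,
    pef_best: float,
    date: Date | None = None,
    predicted: float | None = None,
    equation: str = "nunn_gregg",
) -> LungFunctionAssessment:
    """Bundle staging and PEF evaluation for one measurement session."""
    pct, low = pef_percent_predicted(pef_best, profile, predicted, equation)
    pred = predicted if predicted is not None else predicted_pef(profile, equation)
    return LungFunctionAssessment(
        patient_id=profile.patient_id,
        date=date,
        gold_stage=gold_stage(profile.fev1_pct_pred),
        pef_best=pef_best,
        pef_predicted=pred,
        pef_pct_pred=pct,
        low_pef_flag=low,
    )
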