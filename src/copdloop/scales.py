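"""Scoring and severity banding for the three patient-reported instruments.

CAT (8 items, 0-5 each, total 0-40) measures COPD impact on daily life;
PHQ-9 (9 items, 0-3, total 0-27) screens for depression; GAD-7 (7 items,
0-3, total 0-21) screens for anxiety.  Totals are plain item sums; severity
bands come from the configurable band tables (``config.DEFAULT_CONFIG``),
whose defaults follow the instruments' published cut-points, with the CAT
low/medium boundary at 10/11.  A partial questionnaire is invalid — there
is no item imputation.
"""
from __future__ import annotations

from dataclasses import dataclass

from .models import INSTRUMENT_ITEM_SPEC, Instrument, QuestionnaireResponse

#: full total-score range per instrument
SCORE_RANGE = {"CAT": (0, 40), "PHQ9": (0, 27), "GAD7": (0, 21)}


@dataclass(frozen=True)
class ScaleScore:
    instrument: str
    total: int
    band: str


def validate_band_table(instrument: str, rows: list) -> None:
    """Bands must partition the instrument's full score range: ordered,
    contiguous, no overlap, no gap."""
    lo, hi = SCORE_RANGE[instrument]
    expected_next = lo
    for label, b_lo, b_hi in rows:
        if b_lo != expected_next:
            raise ValueError(
                f"{instrument} band table has a gap or overlap at {b_lo} "
                f"(expected lower bound {expected_next})"
            )
        if b_hi < b_lo:
            raise ValueError(f"{instrument} band {label!r} is empty ({b_lo}-{b_hi})")
        expected_next = b_hi + 1
    if expected_next != hi + 1:
        raise ValueError(
            f"{instrument} band table ends at {expected_next - 1}, "
            f"must cover the full range {lo}-{hi}"
        )


def band_for(instrument: str | Instrument, total: int, bands: dict | None = None) -> str:
    """Severity label for a total score, from the configured band table."""
    from .config import DEFAULT_CONFIG

    name = instrument.value if isinstance(instrument, Instrument) else instrument
    table = (bands or DEFAULT_CONFIG["bands"])[name]
    lo, hi = SCORE_RANGE[name]
    if not lo <= total <= hi:
        raise ValueError(f"{name} total {total} outside {lo}..{hi}")
    for label, b_lo, b_hi in table:
        if b_lo <= total <= b_hi:
            return label
    raise ValueError(f"{name} band table does not cover total {total}")  # pragma: no cover


def _score(instrument: str, items, bands: dict | None) -> ScaleScore:
    n, lo, hi = INSTRUMENT_ITEM_SPEC[instrument]
    items = tuple(int(x) for x in items)
    if len(items) != n:
        raise ValueError(f"{instrument} requires exactly {n} items, got {len(items)}")
    for x in items:
        if not lo <= x <= hi:
            raise ValueError(f"{instrument} item value {x} outside {lo}..{hi}")
    total = sum(items)
    return ScaleScore(instrument, total, band_for(instrument, total, bands))


def score_cat(items, bands: dict | None = None) -> ScaleScore:
    """Score the COPD Assessment Test: 8 items rated 0-5, total 0-40."""
    return _score("CAT", items, bands)


def score_phq9(items, bands: dict | None = None) -> ScaleScore:
    """Score the Patient Health Questionnaire-9: 9 items rated 0-3, total 0-27."""
    return _score("PHQ9", items, bands)


def score_gad7(items, bands: dict | None = None) -> ScaleScore:
    """Score the Generalized Anxiety Disorder-7: 7 items rated 0-3, total 0-21."""
    return _score("GAD7", items, bands)


def score_response(resp: QuestionnaireResponse, bands: dict | None = None) -> ScaleScore:
    """Score an already-validated questionnaire record."""
    return _score(resp.instrument.value, resp.items, bands)
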