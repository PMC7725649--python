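"""Pre/post outcomes analysis and report generation.

The analysis plan mirrors the study design: PEF change is tested with a
paired Student t test and summarized as mean (SD); the three scale totals
(CAT, PHQ-9, GAD-7) are tested with Wilcoxon signed-rank tests and
summarized as median (Q1-Q3); two-sided p-values with significance at
0.05.  Pairing is complete-case on patient id — only patients with both a
baseline and a post measurement enter a test.  The Wilcoxon convention is
zero-difference discard, exact null distribution up to 25 non-zero pairs
and the normal approximation with continuity correction above that.

Adverse events are counted per kind and study period (COPD-related only)
and change is expressed as a percent reduction 100 x (pre - post) / pre.
Rounding follows one central convention: one decimal for outcome
proportions and reductions, nearest integer for demographic proportions.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .models import AdverseEvent, Cohort, Instrument
from .monitoring import ComplianceReport

ALPHA = 0.05

#: centralized formatting table: decimals used when printing each quantity
ROUNDING = {
    "outcome_proportion_pct": 1,
    "demographic_proportion_pct": 0,
    "percent_reduction": 1,
    "mean_sd": 1,
    "median_quartile": 1,
    "p_value": 3,
}


@dataclass(frozen=True)
class OutcomeResult:
    outcome: str
    n_pairs: int
    baseline_summary: str
    post_summary: str
    test_name: str
    statistic: float | None
    p_value: float | None
    note: str | None = None

    @property
    def significant(self) -> bool | None:
        return None if self.p_value is None else bool(self.p_value < ALPHA)


def paired_t(baseline: Sequence[float], post: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Student t test; returns (statistic, p)."""
    res = stats.ttest_rel(post, baseline)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(
    baseline: Sequence[float], post: Sequence[float]
) -> tuple[float | None, float | None]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded; the exact distribution is used up to 25
    non-zero pairs and the normal approximation with continuity correction
    above.  Degenerate input (no non-zero differences) returns (None, None).
    """
    d = np.asarray(post, dtype=float) - np.asarray(baseline, dtype=float)
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        return None, None
    method = "exact" if n_nonzero <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                         alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _mean_sd(x: np.ndarray) -> str:
    d = ROUNDING["mean_sd"]
    return f"{np.mean(x):.{d}f} ({np.std(x, ddof=1):.{d}f})"


def _median_iqr(x: np.ndarray) -> str:
    d = ROUNDING["median_quartile"]
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.{d}f} ({q1:.{d}f}-{q3:.{d}f})"


def paired_outcome_test(
    outcome: str,
    baseline: Mapping[str, float],
    post: Mapping[str, float],
    kind: str = "scale",
) -> OutcomeResult:
    """Complete-case paired comparison for one outcome.

    ``kind='pef'`` uses the paired t test and mean (SD) summaries;
    ``kind='scale'`` uses the Wilcoxon signed-rank test and median (Q1-Q3).
    """
    if kind not in ("pef", "scale"):
        raise ValueError(f"kind must be 'pef' or 'scale', got {kind!r}")
    paired_ids = sorted(set(baseline) & set(post))
    b = np.array([baseline[p] for p in paired_ids], dtype=float)
    a = np.array([post[p] for p in paired_ids], dtype=float)
    if len(paired_ids) < 2:
        return OutcomeResult(
            outcome=outcome, n_pairs=len(paired_ids),
            baseline_summary="-", post_summary="-",
            test_name="paired t test" if kind == "pef" else "Wilcoxon signed-rank test",
            statistic=None, p_value=None,
            note=f"test skipped: only {len(paired_ids)} complete pair(s)",
        )
    if kind == "pef":
        stat, p = paired_t(b, a)
        return OutcomeResult(outcome, len(paired_ids), _mean_sd(b), _mean_sd(a),
                             "paired t test", stat, p)
    stat, p = wilcoxon_signed_rank(b, a)
    note = "no non-zero differences; reported as no change" if stat is None else None
    return OutcomeResult(outcome, len(paired_ids), _median_iqr(b), _median_iqr(a),
                         "Wilcoxon signed-rank test", stat, p, note)


def _first_last(values: list[tuple[datetime.date, float]]) -> tuple[float, float] | None:
    if len(values) < 2:
        return None
    values = sorted(values)
    return values[0][1], values[-1][1]


def outcome_table(cohort: Cohort) -> list[OutcomeResult]:
    """The four-outcome pre/post table from a cohort's record streams.

    Baseline is each patient's earliest record of the outcome and post the
    latest; patients with fewer than two dated records are excluded
    (complete-case pairing, the completer analysis).
    """
    pef_base, pef_post = {}, {}
    for pid, records in cohort.pef.items():
        fl = _first_last([(r.date, r.best) for r in records])
        if fl:
            pef_base[pid], pef_post[pid] = fl
    results = [paired_outcome_test("PEF", pef_base, pef_post, kind="pef")]

    for inst in Instrument:
        base, post = {}, {}
        for pid, records in cohort.questionnaires.items():
            fl = _first_last([(q.date, q.total) for q in records
                              if q.instrument == inst])
            if fl:
                base[pid], post[pid] = fl
        results.append(paired_outcome_test(inst.value, base, post, kind="scale"))
    return results


def percent_reduction(pre: int | float, post: int | float) -> float:
    """Percent decrease from a pre-period count to a post-period count,
    rounded to one decimal.  Undefined when pre is zero."""
    if pre <= 0:
        raise ValueError("percent reduction is undefined when the pre count is 0")
    return round(100.0 * (pre - post) / pre, ROUNDING["percent_reduction"])


def proportion(numerator: int | float, denominator: int | float,
               kind: str = "outcome") -> float:
    """A percentage at the conventional precision: one decimal for outcome
    proportions, nearest integer for demographic proportions."""
    if denominator <= 0:
        raise ValueError("proportion is undefined for a non-positive denominator")
    decimals = (ROUNDING["outcome_proportion_pct"] if kind == "outcome"
                else ROUNDING["demographic_proportion_pct"])
    value = round(100.0 * numerator / denominator, decimals)
    return value if decimals else float(int(value))


@dataclass(frozen=True)
class AdverseEventSummary:
    counts: dict[str, dict[str, int]]          # period -> kind -> count
    reductions: dict[str, float | None]        # kind -> percent reduction

    def count(self, period: str, kind: str) -> int:
        return self.counts.get(period, {}).get(kind, 0)


def adverse_event_summary(events: Sequence[AdverseEvent]) -> AdverseEventSummary:
    """Totals by kind and period plus pre-to-study percent reductions.

    Only COPD-related events are counted; a reduction is None when the
    pre-study count is zero (undefined).
    """
    counts: dict[str, dict[str, int]] = {"pre_study": {}, "study": {}}
    for ev in events:
        if not ev.copd_related:
            continue
        per = counts[ev.period.value]
        per[ev.kind.value] = per.get(ev.kind.value, 0) + 1
    reductions: dict[str, float | None] = {}
    for kind in ("clinic_visit", "hospitalization"):
        pre = counts["pre_study"].get(kind, 0)
        post = counts["study"].get(kind, 0)
        reductions[kind] = percent_reduction(pre, post) if pre > 0 else None
    return AdverseEventSummary(counts=counts, reductions=reductions)


def build_report(
    outcomes: list[OutcomeResult] | None = None,
    compliance_overall: Mapping[str, ComplianceReport] | None = None,
    exacerbations=None,
    adverse: AdverseEventSummary | None = None,
    demographics: Mapping[str, object] | None = None,
) -> str:
    """Render a deterministic human-readable report; sections whose stage
    output is missing are marked absent rather than failing."""
    lines: list[str] = ["COPD closed-loop management report", "=" * 36, ""]

    lines.append("Demographics")
    if demographics:
        for key, value in demographics.items():
            lines.append(f"  {key}: {value}")
    else:
        lines.append("  [section absent: no demographics provided]")
    lines.append("")

    lines.append("Clinical outcomes (baseline vs after management)")
    if outcomes:
        for r in outcomes:
            p = "-" if r.p_value is None else f"{r.p_value:.{ROUNDING['p_value']}f}"
            lines.append(
                f"  {r.outcome}: {r.baseline_summary} -> {r.post_summary}"
                f"  [{r.test_name}, n={r.n_pairs}, P={p}]"
                + (f"  ({r.note})" if r.note else "")
            )
    else:
        lines.append("  [section absent: no outcome table provided]")
    lines.append("")

    lines.append("Compliance")
    if compliance_overall:
        pooled = np.array([r.pooled_pct for r in compliance_overall.values()])
        q1, med, q3 = np.percentile(pooled, [25, 50, 75])
        lines.append(
            f"  overall pooled compliance: median {med:.1f}% (IQR {q1:.1f}%-{q3:.1f}%),"
            f" n={len(pooled)}"
        )
    else:
        lines.append("  [section absent: no compliance reports provided]")
    lines.append("")

    lines.append("Acute exacerbations")
    if exacerbations is not None:
        lines.append(
            f"  suspected {exacerbations.total_suspected}, confirmed "
            f"{exacerbations.total_confirmed}, rejected {exacerbations.total_rejected}"
        )
        lines.append(
            f"  per patient: median {exacerbations.median:.1f} "
            f"(IQR {exacerbations.q1:.1f}-{exacerbations.q3:.1f})"
        )
    else:
        lines.append("  [section absent: no exacerbation summary provided]")
    lines.append("")

    lines.append("Adverse events (COPD-related)")
    if adverse is not None:
        for kind in ("death", "hospitalization", "clinic_visit"):
            pre = adverse.count("pre_study", kind)
            post = adverse.count("study", kind)
            red = adverse.reductions.get(kind)
            red_txt = f", reduction {red:.1f}%" if red is not None else ""
            lines.append(f"  {kind}: pre {pre} -> study {post}{red_txt}")
    else:
        lines.append("  [section absent: no adverse-event summary provided]")

    return "\n".join(lines) + "\n"
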