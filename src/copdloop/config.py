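"""Central run-time configuration.

Every tunable rule of the pathway lives here as data, not code: severity
band tables for the three instruments, GOLD spirometric thresholds, the
hierarchical-management rule table, warning thresholds, monitoring
prescription and follow-up intervals, and the PEF reference-equation
choice.  ``load_config`` deep-merges a user YAML file over the defaults,
so any of the pathway's rules can be overridden without touching code.
"""
from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    # Severity bands: label -> [inclusive lower, inclusive upper]
    "bands": {
        "CAT": [["low", 0, 10], ["medium", 11, 20], ["high", 21, 30], ["very high", 31, 40]],
        "PHQ9": [["minimal", 0, 4], ["mild", 5, 9], ["moderate", 10, 14],
                 ["moderately severe", 15, 19], ["severe", 20, 27]],
        "GAD7": [["none", 0, 4], ["mild", 5, 9], ["moderate", 10, 14], ["severe", 15, 21]],
    },
    # GOLD spirometric staging on FEV1 % predicted: stage 1 at or above the
    # first cut, stage 2 at or above the second, ... stage 4 below the last.
    "gold_thresholds": [80.0, 50.0, 30.0],
    "pef": {
        "reference_equation": "nunn_gregg",
        "low_pct_pred_threshold": 80.0,      # flag strictly below this % predicted
        "variability_metric": "amplitude_percent_mean",  # or "cv"
    },
    # Hierarchical management: a risk axis crossed with a symptom axis.
    "risk_rules": {
        "high_risk_if": {
            "exacerbations_per_6mo": 2,   # at or above
            "hospitalizations": 1,        # at or above
            "gold_stage": 3,              # at or above
        },
        "symptomatic_if_cat_at_least": 10,
        # (risk axis, symptom axis) -> management level
        "levels": {
            "low_risk,low_symptom": {
                "level": 1, "label": "low",
                "followup_interval_days": 14, "records_per_stream_per_month": 2},
            "low_risk,symptomatic": {
                "level": 2, "label": "symptomatic",
                "followup_interval_days": 14, "records_per_stream_per_month": 2},
            "high_risk,low_symptom": {
                "level": 3, "label": "high_risk",
                "followup_interval_days": 7, "records_per_stream_per_month": 2},
            "high_risk,symptomatic": {
                "level": 4, "label": "high_risk_symptomatic",
                "followup_interval_days": 7, "records_per_stream_per_month": 2},
        },
    },
    "exacerbation": {
        "major_weight": 5,
        "minor_weight": 1,
        "score_threshold": 6,          # a day flags when score is strictly above
        "min_consecutive_days": 2,
        "gap_tolerance_days": 0,       # 0 = a missing diary day breaks a run
    },
    "monitoring": {
        "streams": ["PEF", "CAT", "PHQ9", "GAD7"],
        "records_per_stream_per_month": 2,   # biweekly prescription
        "low_compliance_threshold_pct": 50.0,
        "routine_followup_interval_days": 14,
        "extra_followup_offset_days": 1,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Return the default configuration, with ``path`` (YAML) merged over it."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _deep_merge(cfg, user)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Fail fast on rule tables that do not cover their domain."""
    from .scales import validate_band_table  # deferred: scales imports config

    for instrument, rows in cfg["bands"].items():
        validate_band_table(instrument, rows)

    levels = cfg["risk_rules"]["levels"]
    expected = {f"{r},{s}" for r in ("low_risk", "high_risk")
                for s in ("low_symptom", "symptomatic")}
    missing = expected - set(levels)
    if missing:
        raise ValueError(f"risk rule table does not cover: {sorted(missing)}")

    thr = cfg["gold_thresholds"]
    if sorted(thr, reverse=True) != list(thr) or len(thr) != 3:
        raise ValueError("gold_thresholds must be 3 strictly decreasing cut-points")
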