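"""Compute compliance, raise warnings and build the follow-up schedule.

Compliance is uploaded records over prescribed records (2 per stream per
month), capped at 100 %.  Warnings fire on suspected exacerbations, low
PEF, low monthly compliance and silent streams; each unhandled warning
books one extra follow-up on top of the routine 14-day cadence.
"""
import datetime

from copdloop import (
    compliance,
    generate_warnings,
    prescribed_counts,
    schedule_followups,
)

D = datetime.date
presc = prescribed_counts(1)                      # one month: 2 per stream
actual = {"PEF": 3, "CAT": 1, "PHQ9": 0, "GAD7": 0}
report = compliance(actual, presc, "P1", (D(2018, 1, 1), D(2018, 1, 31)))

print("per-stream capped ratios:",
      {s: f"{c.capped_ratio_pct:.0f}%" for s, c in report.streams.items()})
print(f"pooled monthly compliance: {report.pooled_pct:.1f}%")

warnings = generate_warnings(compliance_reports=[report])
for w in warnings:
    print(f"warning {w.kind} on {w.date}: {w.payload_dict()}")

sched = schedule_followups("P1", D(2018, 1, 1), horizon_days=56, warnings=warnings)
print(f"{len(sched.routine)} routine + {len(sched.extra)} extra follow-ups:")
for ev in sched.events:
    print(f"  {ev.due_date}  {ev.kind}")
# Over-recording PEF still caps at 100%; the 37.5% pooled month is below the
# 50% threshold, so a low-compliance warning (plus missed-upload warnings for
# the silent scales) each trigger an extra contact the following day.
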