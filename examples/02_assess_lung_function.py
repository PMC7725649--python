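"""Evaluate home peak-flow sessions against a predicted value.

A session keeps the highest of up to three attempts; the pathway flags a
session when the best value falls strictly below 80 % of the predicted
PEF, and watches within-window variability as an early-warning index.
"""
import datetime

from copdloop import (
    PatientProfile,
    assess_patient,
    best_of_three,
    classify_risk,
    pef_variability,
)

profile = PatientProfile(
    patient_id="P0001", age=62, sex="male", height_cm=170,
    smoking_status="ex", fev1_pct_pred=55.0, fev1_fvc=60.0,
    enrollment_date=datetime.date(2017, 10, 1),
)

best = best_of_three((320, 340, 335))
a = assess_patient(profile, best, date=datetime.date(2017, 10, 15))
print(f"best of three attempts : {a.pef_best:.0f} L/min")
print(f"predicted PEF          : {a.pef_predicted:.0f} L/min (Nunn-Gregg)")
print(f"percent of predicted   : {a.pef_pct_pred:.1f}%  low-PEF flag: {a.low_pef_flag}")
print(f"GOLD stage (FEV1 55%)  : {a.gold_stage}")

series = [(datetime.date(2017, 10, d), v) for d, v in [(10, 400.0), (12, 300.0)]]
print(f"PEF variability (7d)   : {pef_variability(series, 7):.1f}%")

level = classify_risk(a.gold_stage, cat_total=17, exacerbation_history=2,
                      hospitalizations=0)
print(f"management level       : {level.level} ({level.label}), "
      f"follow-up every {level.followup_interval_days} days")
# A flagged session (<80% predicted) plus frequent exacerbations place the
# patient on the tight follow-up arm of the management grid.
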