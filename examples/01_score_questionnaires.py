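"""Score the three patient-reported instruments and band their severity.

The management pathway tracks quality of life with the CAT (8 items, 0-5),
depression with the PHQ-9 (9 items, 0-3) and anxiety with the GAD-7
(7 items, 0-3).  Totals are item sums; the severity band drives how the
result is read clinically.
"""
from copdloop import score_cat, score_gad7, score_phq9

cat = score_cat([3, 2, 2, 2, 2, 2, 2, 2])
phq = score_phq9([1, 1, 1, 1, 1, 1, 0, 0, 0])
gad = score_gad7([1, 1, 1, 1, 0, 0, 0])

for s in (cat, phq, gad):
    print(f"{s.instrument:5s} total={s.total:2d}  band={s.band}")

# A CAT of 17 sits in the medium-impact band (11-20); PHQ-9 of 6 is mild
# depression (5-9); GAD-7 of 4 is still below the anxiety-disorder cut (0-4).
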