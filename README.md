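# copdloop

A closed-loop management engine for chronic obstructive pulmonary disease
(COPD) remote monitoring, written for digital-health researchers and
engineers who need the quantified rules of such a pathway — questionnaire
scoring, peak-flow evaluation, symptom-diary exacerbation detection,
compliance computation, warning generation and follow-up scheduling — as a
testable library rather than a deployed app. A synthetic-cohort simulator
with known ground truth and a study-style outcomes-analysis stage make the
whole loop reproducible without any real patient data.

## The rules at the core

**Symptom score and exacerbation detection.** Each diary day records seven
booleans. With major symptoms M = {dyspnea, sputum purulence, sputum volume}
and minor symptoms m = {nasal discharge/congestion, sore throat, cough,
wheeze}, the daily score is

```
S = 5 · #majors + 1 · #minors            (0 ≤ S ≤ 19)
```

A *suspected exacerbation* is any maximal run of calendar-consecutive
recorded days with S > 6 lasting ≥ 2 days; a missing diary day breaks a
run (configurable), and every suspected episode requires clinician
confirmation before it counts as an outcome. Of the 2⁷ = 128 possible
symptom vectors, exactly 97 exceed the threshold.

**Peak flow.** A session keeps the best of up to three attempts; the
percent of predicted is 100 · PEF_best / PEF_pred (default reference:
Nunn & Gregg 1989, pluggable), with a low-PEF flag strictly below 80 %.
Variability over a trailing window defaults to 100 · (max − min)/mean.

**Compliance.** With prescription 2 records per stream (PEF, CAT, PHQ-9,
GAD-7) per calendar month, per-stream compliance is
min(actual/prescribed, 1) and the pooled value is
Σ min(actualₛ, prescribedₛ) / Σ prescribedₛ — over-recording caps at 100 %.

**Loop closure.** Risk classification crosses a risk axis (≥ 2
exacerbations/6 months, ≥ 1 hospitalization, or GOLD ≥ 3) with a symptom
axis (CAT ≥ 10); routine follow-up runs every 14 days and each unhandled
warning (suspected exacerbation, low PEF, monthly compliance < 50 %,
silent stream) books exactly one extra contact the next day.

**Outcomes analysis.** Pre/post change in PEF uses a paired Student *t*
test, mean (SD); the three scale totals use Wilcoxon signed-rank tests,
median (Q1–Q3); complete-case pairing, two-sided α = 0.05. Adverse-event
change is 100 · (pre − post)/pre.

## Worked example

```python
>>> import datetime
>>> from copdloop import SymptomDiaryEntry, score_stream, detect_episodes
>>> D = datetime.date
>>> diary = [
...     SymptomDiaryEntry(patient_id="P1", date=D(2018, 1, 1), cough=True),
...     SymptomDiaryEntry(patient_id="P1", date=D(2018, 1, 2), dyspnea=True,
...                       sputum_volume=True, cough=True),
...     SymptomDiaryEntry(patient_id="P1", date=D(2018, 1, 3), dyspnea=True,
...                       sputum_purulence=True),
...     SymptomDiaryEntry(patient_id="P1", date=D(2018, 1, 4), cough=True),
... ]
>>> [(s.date.day, s.score, s.flagged) for s in score_stream(diary)]
[(1, 1, False), (2, 11, True), (3, 10, True), (4, 1, False)]
>>> detect_episodes(score_stream(diary))[0].peak_score
11
```

Days 2 and 3 score 11 and 10 (two majors each): both exceed 6 on
consecutive recorded days, so one suspected episode spanning 2018-01-02 to
2018-01-03 is raised; the flanking low-score days bound it.

The `examples/` directory holds one short script per capability
(scoring, lung-function assessment, detection, compliance/warnings/
scheduling, full simulate-and-analyze); each prints its numbers with a
note on what they mean. A thin CLI mirrors the stages:

```bash
copdloop simulate --seed 1 --out scratch/cohort
copdloop detect scratch/cohort
copdloop analyze scratch/cohort
```

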