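"""Detect suspected acute exacerbations from a symptom diary.

Major symptoms (dyspnea, sputum purulence, sputum volume) score 5 points,
minor ones (nasal discharge/congestion, sore throat, cough, wheeze) score
1; a suspected exacerbation is a score above 6 on at least 2 consecutive
recorded days, and then needs clinician confirmation.
"""
import datetime

from copdloop import (
    SymptomDiaryEntry,
    confirm_episode,
    detect_episodes,
    exacerbation_summary,
    score_stream,
)

D = datetime.date
diary = [
    SymptomDiaryEntry(patient_id="P1", date=D(2018, 1, 1), cough=True),
    SymptomDiaryEntry(patient_id="P1", date=D(2018, 1, 2), dyspnea=True,
                      sputum_volume=True, cough=True),            # score 11
    SymptomDiaryEntry(patient_id="P1", date=D(2018, 1, 3), dyspnea=True,
                      sputum_purulence=True),                     # score 10
    SymptomDiaryEntry(patient_id="P1", date=D(2018, 1, 4), cough=True),
]

scores = score_stream(diary)
print("daily scores:", [(s.date.day, s.score, s.flagged) for s in scores])

episodes = detect_episodes(scores)
for ep in episodes:
    print(f"suspected episode {ep.start_date} .. {ep.end_date}, "
          f"peak score {ep.peak_score}")

confirmed = [confirm_episode(ep, "confirm") for ep in episodes]
summary = exacerbation_summary(confirmed, ["P1"])
print(f"confirmed episodes: {summary.total_confirmed}, "
      f"cohort median {summary.median:.1f}")
# Days 2-3 both exceed 6 points, so one suspected episode is raised; after
# clinician confirmation it enters the outcome counts.
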