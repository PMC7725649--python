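# Methods

This note documents the models and conventions behind `copdloop`: what each
stage computes, the tunable parameters and their defaults, what the
synthetic cohort does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Records and conventions

Dates are ISO-8601 calendar dates. Every interval is closed on both ends
and measured in whole days, matching the one-day granularity of the symptom
diary. Duplicate same-day rows are normalized conservatively toward
detection: symptom entries are OR-merged per symptom, peak-flow sessions
keep the record with the higher best value (the same convention as taking
the highest of repeated attempts), and questionnaires keep the latest row.
Validation rejects rows that violate a stated invariant — it never silently
drops them — and reports the file and row number. Enrollment requires age
≥ 40 years; FEV1 % predicted must lie in (0, 200] and FEV1/FVC in (0, 100].

Canonical storage is long-format per-patient streams; the delimited (CSV)
and structured (JSON) layouts carry identical content and round-trip
exactly. Optional columns absent for every record are omitted from the
file and tolerated on reload.

## Instrument scoring

CAT (8 items, 0–5), PHQ-9 (9 items, 0–3) and GAD-7 (7 items, 0–3) totals
are plain item sums; partial questionnaires are invalid (no imputation).
Severity bands are configuration data that must partition each
instrument's full range with no gap or overlap. Defaults:

| instrument | bands |
|---|---|
| CAT | low 0–10, medium 11–20, high 21–30, very high 31–40 |
| PHQ-9 | minimal 0–4, mild 5–9, moderate 10–14, moderately severe 15–19, severe 20–27 |
| GAD-7 | none 0–4, mild 5–9, moderate 10–14, severe 15–21 |

The CAT low/medium boundary is set at 10/11. Some published tables treat
10 as the symptomatic cut instead; the table is user-overridable and the
boundary choice is deliberately explicit because scores of exactly 10 are
common.

## Lung function and risk classification

GOLD spirometric staging uses FEV1 % predicted at cuts 80/50/30 (stage 1
at ≥ 80 down to stage 4 below 30); the cuts are configuration, not code.
The predicted PEF comes from a pluggable reference equation; the shipped
default is the Nunn & Gregg (1989) adult regression on ln(PEF, L/min) by
sex, age and height, chosen because it is the standard equation for
hand-held L/min peak-flow meters. Any callable `profile → L/min` can be
registered, and an explicitly supplied predicted value always bypasses the
equation, so no downstream result depends on the equation choice. The
low-PEF flag is a strict inequality: exactly 80 % of predicted does not
flag.

PEF variability over a trailing window defaults to amplitude-percent-mean,
100 · (max − min)/mean, with the coefficient of variation available by
config; at least two values inside the window are required.

The hierarchical-management grid crosses a risk axis (high iff ≥ 2
exacerbations per 6 months, or ≥ 1 hospitalization, or GOLD ≥ 3) with a
symptom axis (CAT ≥ 10), giving four ordered levels with follow-up
intervals 14/14/7/7 days and a uniform monitoring prescription of 2
records per stream per month. This default grid is a GOLD-style stand-in:
the deployed pathway's exact rule table is not public, so the grid is
shipped as data, validated for completeness at configuration load, and
checked (by enumeration) to be total and monotone — worsening any single
input never lowers the level.

## Exacerbation detection

Daily score S = 5·(major count) + 1·(minor count) ∈ [0, 19]; a day flags
when S > 6, never at 6. A suspected episode is a maximal run of
calendar-consecutive recorded flagged days of length ≥ 2. Two policies
govern missing diary days: the default treats an unrecorded day as
breaking a run (conservative, invents no data); a gap-tolerant variant may
bridge up to a configured number of unrecorded days for sensitivity
analysis. A recorded non-flagged day always breaks a run, and two flagged
runs separated by one are distinct episodes — no merge window. An
episode's end is its last flagged recorded day; there is no convalescence
tail. Episode confirmation is a one-shot state transition
(suspected → confirmed/rejected) that preserves the episode data and the
rejection reason; only confirmed episodes enter outcome counts, summarized
per patient with the cohort median and quartiles (linear-interpolation
percentiles).

## Monitoring, warnings and scheduling

Compliance is computed per calendar-month window anchored at enrollment,
with prescription 2 records per stream per month (the biweekly plan under
a monthly reporting convention; a day-counted 14-day-cycle prescription
can be configured instead). Ratios cap at 100 %, and the pooled ratio uses
capped per-stream actuals over summed prescriptions, so capping is
idempotent. Cohort summaries report per-month median and quartiles for two
populations: all enrolled, where months at or after a patient's exit count
as 0 %, and completers only.

Warnings are a pure function of the monitored data: one
`suspected_exacerbation` per detected episode, `low_pef` below 80 % of
predicted, `low_compliance` below a 50 % monthly pooled ratio, and
`missed_upload` for a stream silent through a prescription month. The
80 % and 50 % thresholds are configured defaults, not empirically derived.
Warning generation deduplicates on (patient, kind, date, payload), so
re-running the engine is idempotent. Routine follow-ups fall every 14 days
from enrollment (k·interval ≤ horizon); every unhandled warning books
exactly one extra contact, by default the day after the warning, and
extras never displace routine events.

## The synthetic cohort

The generator's defaults are the study conditions of a 56-patient,
6-month community cohort:

* demographics — 92 % male, age ~ N(61.82, 6.09²) truncated at 40; GOLD
  stage mix 18/41/15/26 %, FEV1 % predicted uniform within the stage band;
  heights N(168, 6²) cm for men, N(156, 6²) for women; education and
  smoking mixes matching the completer table;
* dropout — monthly hazard 0.0577, i.e. ≈ 30 % exit by month 6; an
  exiting patient contributes no records from the exit month onward;
* exacerbations — per-patient count ~ NegBin(mean 2 per 6 months,
  k = 1.5 for overdispersion), duration 1 + Geometric(mean 3) days
  (mean 4, minimum 2), placed uniformly with ≥ 2 quiet days between
  episodes so neighbouring runs stay distinct;
* symptoms — outside episodes, majors fire at 0.02/day and minors at
  0.08/day; inside an episode each day is, with probability
  `p_flag_in_episode` (default 0.9), drawn from an elevated distribution
  and then forced above the detection threshold if the draw fell short, so
  that with flag probability 1 every in-episode day is detectable by
  construction;
* uploads — each diary day and each biweekly slot (two per calendar-month
  window, aligning the emission cadence with the monthly prescription) is
  recorded with the patient's adherence probability, drawn once per
  patient from Beta(6, 0.8) (median ≈ 0.92) or fixed by config;
* peak flow — baseline % predicted by stage (85/65/45/30, SD 8), a 2.4 %
  monthly multiplicative decline, a 15 % dip during episodes, and
  lognormal measurement noise (σ = 0.04 on the log scale);
* questionnaires — per-patient latent severity p ~ baseline/total_max +
  N(0, 0.08²) clipped to [0.02, 0.95]; items ~ Binomial(item max, p);
  the improvement effect lowers p linearly over the horizon by
  (points · effect)/total_max, with default point drops CAT 3, PHQ-9 2,
  GAD-7 1 and `improvement_effect = 0` disabling any systematic change;
* adverse events — per-patient Poisson counts with pre-study means
  115/39 clinic visits and 69/39 hospitalizations and study-period means
  52/39 and 19/39 (scaled by the observed fraction for dropouts), plus
  non-COPD noise events that the analysis stage must filter out.

All draws flow from `numpy.random.default_rng` seeded by the single config
seed, so identical configurations give byte-identical output files.

What the generator does **not** emulate: within-patient symptom
autocorrelation beyond the episode indicator (real diaries are stickier),
seasonal effects, reactive behaviour (adherence does not respond to
warnings or follow-ups), treatment effects on episode frequency, and
informative dropout. Passing recovery tests therefore shows the engine's
rules are implemented correctly under the stated statistical shape — not
that the pathway would achieve the same clinical outcomes on real
patients.

A known consequence of the defaults: a NegBin with mean 2 has median 1, so
the simulated cohort's median detected exacerbation count per 6 months is
about 1 under realistic adherence, lower than the clinical median of 2
reported for cohorts of this severity mix; the mean burden, not the
quartiles, is what the generator matches.

## Outcomes analysis

Pairing is complete-case on patient id: baseline is each patient's
earliest dated record of an outcome, post the latest, and patients with
fewer than two records are excluded (the completer analysis). PEF uses the
paired Student *t* test with mean (SD) summaries; scale totals use
two-sided Wilcoxon signed-rank tests with median (Q1–Q3) summaries and
α = 0.05. The Wilcoxon convention — genuinely open, since test software
defaults differ — is: zero differences discarded, average ranks for ties,
exact null distribution up to 25 non-zero pairs, normal approximation with
continuity correction above. Under a zero improvement effect this
convention rejects at 4–5.5 % across the three scales in 1,000-replicate
simulations at n = 39 (slightly conservative for the discretest scale, as
expected with the correction). Fewer than two complete pairs skips a test
with an explicit reason; all-zero differences are reported as "no change"
rather than a p-value.

Percent reductions are 100 · (pre − post)/pre, undefined (an error) at
pre = 0. Rounding is centralized: one decimal for outcome proportions,
reductions and summaries, nearest integer for demographic proportions,
three decimals for p-values. Reports are pure functions of their inputs;
missing stages render as explicitly absent sections.

## Problem sizes used in checks

The test suite and acceptance script use: exhaustive enumeration of the
128 symptom vectors and of the risk-grid domain; 1,000 random gapped
streams for detector/oracle equivalence; a 50-patient, 6-month cohort for
full-sensitivity recovery; 10,000 profiles for demographic-mix checks; and
1,000 replicates at n = 39 for the type-I calibration of the scale tests.
These sizes give binomial standard errors comfortably inside the asserted
tolerances (e.g. ±0.7 points on a 5 % rejection rate).
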