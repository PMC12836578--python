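# eprotriage

Remote patient monitoring of melanoma patients on immune checkpoint
inhibitors (ICI) relies on weekly electronic patient-reported outcomes
(ePRO): an 11-item symptom questionnaire graded on CTCAE-style scales,
converted by a rule into a **green / orange / red** triage score, with
orange and red scores ("alert scores") triggering an oncology-nurse
call.  `eprotriage` implements that instrument and triage algorithm, the
alert workflow with its response-deadline semantics, and the
retrospective framework used to evaluate how well such a system detects
grade ≥2 immune-related adverse events (IrAEs) — plus a seeded
synthetic-cohort simulator so the whole pipeline can be exercised and
tested without access to patient data.

It is aimed at biostatisticians and clinical-informatics teams who run
or evaluate ePRO alert systems in immuno-oncology.

## The triage rule and the evaluation model

Each of the 11 symptoms (fever, fatigue, headache, shortness of breath,
nausea/vomiting, rash, diarrhea, decreased appetite, numbness/tingling,
general pain, blurred vision) is graded 0–3 (0–4 for nausea/vomiting and
diarrhea) and bucketed: absent/slight (grade 0–1), moderate (grade 2),
severe (grade 3–4).  With *m* moderate and *s* severe symptoms:

```
green   iff  m = 0 and s = 0
orange  iff  1 ≤ m ≤ 2 and s = 0
red     iff  s ≥ 1  or  m ≥ 3
```

A configurable scoring policy can escalate individual items (e.g. treat
any grade-2 diarrhea as severe, turning the score red) at the bucketing
step, so *m*/*s* counts stay meaningful.

For evaluation, a grade ≥2 IrAE is **correctly detected** when an alert
questionnaire reporting a moderate/severe *related* symptom precedes its
diagnosis within a linkage window (default 30 days); among successive
qualifying alerts only the first counts.  The confusion scheme is
mixed-unit, as in the deployment study: TP and FN are counted per IrAE
event, FP and TN per questionnaire, with

```
TN = green questionnaires − missed events
Se = TP/(TP+FN)   Sp = TN/(TN+FP)   PPV = TP/(TP+FP)   NPV = TN/(TN+FN)
```

each with a Wilson score 95% CI.  The framework also produces the
miss-reason taxonomy (blood-test-only disorder, symptoms not in the
instrument, questionnaire not completed, symptoms not reported), the
six-category false-alert cause summary, and days-saved statistics
relative to the next scheduled visit.

## Worked example

```python
import datetime as dt
import eprotriage as ep
from eprotriage.model import ITEM_IDS, Questionnaire, SymptomResponse

grades = {i: 0 for i in ITEM_IDS} | {"fatigue": 2, "general_pain": 2}
q = Questionnaire("q-0017", "p-003", dt.datetime(2021, 3, 2, 10, 0),
                  tuple(SymptomResponse(i, grades[i]) for i in ITEM_IDS))
score = ep.score_questionnaire(ep.validate_questionnaire(q))
# TriageScore(color=<Color.ORANGE: 'orange'>, n_moderate=2, n_severe=0)

alert = ep.raise_alert(score, q.questionnaire_id, q.completed_at)
# respond window: 2021-03-03 10:00 to 2021-03-04 10:00  (24–48 h)

for name, m in ep.diagnostic_metrics(ep.reference_confusion_counts()).items():
    print(f"{name:12s} {m.numerator}/{m.denominator} = {100*m.point:.1f}% "
          f"(95% CI {100*m.ci_low:.1f}–{100*m.ci_high:.1f}%)")
```

prints

```
sensitivity  27/69 = 39.1% (95% CI 28.5–50.9%)
specificity  4352/5113 = 85.1% (95% CI 84.1–86.1%)
ppv          27/788 = 3.4% (95% CI 2.4–4.9%)
npv          4352/4394 = 99.0% (95% CI 98.7–99.3%)
```

Two moderate symptoms give an orange score — a nurse call within
24–48 h.  The metrics are the deployment cohort's headline performance,
rebuilt from its published aggregate counts: the system caught 27 of 69
grade ≥2 IrAEs (most misses were blood-test-only disorders invisible to
a symptom questionnaire), and the near-perfect NPV means a green score
is a reliable sign of no impending IrAE.

## Command line

```
eprotriage simulate --seed 17 --n-patients 50 --out cohort/
eprotriage score    --in cohort/ --out scores.csv
eprotriage evaluate --in cohort/ --window 30 --out report.json
eprotriage report   --report report.json --out tables/
```

`simulate` writes the standard CSV bundle (patients, questionnaires,
IrAE registry, visits) plus ground-truth annotations; `evaluate` runs
the full linkage and metric pipeline; `report` renders TSV tables.

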