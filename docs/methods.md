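# Methods

## Instrument and triage score

The instrument is an 11-item weekly symptom questionnaire for melanoma
patients on immune checkpoint inhibitors, with response options mapped
to CTCAE v5 / PRO-CTCAE-style grades.  Items default to a 0–3 scale;
nausea/vomiting and diarrhea extend to grade 4, the two items whose
CTCAE analogues carry an outpatient-reportable grade 4.  Because the
triage rule only distinguishes grade ≤1 / =2 / ≥3, the per-item ceiling
assignment cannot change any score; ceilings are configurable per item
so any assignment can be expressed, and they bound validation only.

Responses are bucketed absent/slight (0–1), moderate (2), severe (3–4)
and the colour follows from the moderate count *m* and severe count
*s*: green (*m*=*s*=0), orange (1≤*m*≤2, *s*=0), red (*s*≥1 or *m*≥3).
The three regions partition the (*m*, *s*) plane, so every validated
questionnaire maps to exactly one colour, and the score is monotone in
every single response grade — both properties are enforced by tests
(brute-force enumeration oracle plus hypothesis property tests).

Policy variants escalate selected items at the *bucketing* step (item
grade ≥ threshold ⇒ severe) rather than recolouring post hoc.  This
keeps *m*/*s* interpretable and makes the variant proposed for
potentially severe colitis — any grade-2 diarrhea scores red —
expressible as `ScoringPolicy(escalation_overrides={"diarrhea": 2})`.

## Alert workflow

Orange alerts must be answered within 24–48 h of effective receipt, red
alerts immediately.  Alerts are handled 09:00–16:30; a questionnaire
arriving outside that window is timestamped at the next opening (next
day 09:00).  Weekends are treated as working days by default — the
deployed workflow states no weekend rule — with a `weekends_off`
option.  Reminders for uncompleted questionnaires repeat every 7 days
until completion or discontinuation (count configurable, default
unlimited), matching a weekly instrument's cadence.  Systematic nurse
calls sit on a fixed 28-day grid from enrollment; calendar-month
anchoring was rejected for determinism.

## Linkage and the mixed-unit confusion scheme

A grade ≥2 IrAE is detected by the earliest alert questionnaire that
(a) precedes the diagnosis date, (b) by at most `window_days`
(default 30 — observed lead times in deployment spanned 0–25 days), and
(c) reports a moderate/severe grade on a related item.  Ties on the
same calendar day resolve to the lower questionnaire id.  Later
qualifying alerts, and related alerts up to `window_days` *after* the
diagnosis, are labelled `alert_prior_irae` and excluded from the
false-alert pool.  One questionnaire may detect several simultaneous
events.

Relatedness is configuration, not code: a packaged YAML file maps each
IrAE category to its questionnaire items (e.g. skin toxicity → rash;
colitis → diarrhea, nausea/vomiting, decreased appetite).  An event's
explicit `related_items` overrides the map.  An *asymptomatic* event (a
blood-test disorder without clinical impact) never inherits the
category map: a laboratory-only thyroiditis has no related symptoms, so
a coincidental fatigue alert cannot "detect" it.  Miss reasons are
assigned in a fixed order: blood-test-only first, then no questionnaire
completed in the window, then related symptoms outside the instrument,
else symptoms present but not reported.

The confusion tally is mixed-unit: TP/FN per event, FP/TN per
questionnaire, TN = greens − missed events (each missed event is
charged to one green questionnaire).  This is the unique scheme that
reproduces all four published metrics simultaneously
(27/69 = 39.1%, 4352/5113 = 85.1%, 27/788 = 3.4%, 4352/4394 = 99.0%).
A pure questionnaire-level alternative (`scheme="questionnaire"`,
TP = detecting questionnaires, TN = all greens) is provided for
sensitivity analyses only.

Confidence intervals are Wilson score intervals
(statsmodels' `proportion_confint`, boundary cases clamped to exact
0/1); tests verify the implementation against an independent
closed-form evaluation.  Clopper–Pearson is available via
`ci_method="exact"`.  Wilson reproduces the published sensitivity lower
bound (28.5%) and the specificity/NPV intervals to one decimal; the
published sensitivity *upper* bound (50.91%) differs from Wilson
(50.93%) at the second decimal and the published all-event PPV lower
bound (2.7%) differs from Wilson (2.4%), so the original interval
method is evidently not exactly Wilson everywhere and those two digits
are asserted only to |Δ| ≤ 0.05 / not asserted.  Likewise the
symptomatic-only NPV is printed as 99.8% but no consistent FN count
reproduces it exactly (11 symptomatic misses give 4383/4394 = 99.75%);
the package computes and reports its own value without asserting the
printed one.

Zero-denominator metrics are returned as undefined (`point is None`),
never fabricated.  A cohort in which missed events outnumber green
questionnaires raises `InconsistentCohortError` rather than producing a
negative TN.

Days saved by alert-triggered management = (first scheduled visit
strictly after the detecting questionnaire) − diagnosis date, floored
at 0; undefined (and excluded from summaries) when no later visit
exists.

## Published aggregate counts

Patient-level data from the deployment cohort are not public.  The
package ships its published aggregate tallies (5202 questionnaires:
4394 green, 661 orange, 122 red, 25 alerts tied to already-diagnosed
events; 69 grade ≥2 IrAEs: 27 detected, 42 missed of which 31
blood-test-only; 761 false alerts with the six-category cause counts)
as a JSON data file.  All headline quantities are *recomputed* from
those counts at run time; nothing beyond the raw tallies is stored.
One arithmetic note: the deployment report quotes an overall alert rate
of 15.0% while 783/5202 = 15.05%.

## Synthetic-cohort generator

The simulator emulates the deployment conditions; its defaults are the
published rates and sizes, fixed once:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 136 | cohort size as deployed |
| `followup_weeks_median` / `_sigma` | 46 / 0.85 | lognormal follow-up, truncated to 1–227 weeks |
| `adherence_prob` | 0.89 | weekly completion probability |
| `regimen_combo_frac` | 0.096 | ipilimumab+nivolumab fraction |
| `irae_patient_prob` | 0.368 | patients with ≥1 grade ≥2 IrAE |
| `extra_irae_mean` | 0.38 | Poisson mean extra events per affected patient (69 events / 50 patients) |
| `blood_only_frac` | 0.449 | blood-test-only fraction of events |
| `grade34_frac` | 0.246 | grade 3–4 fraction of events |
| `symptom_signature_strength` | 0.75 | probability a symptomatic event lifts related items to grade ≥2 the week before diagnosis |
| `false_alert_rate` | 0.146 | per-questionnaire false-alert probability |
| `red_false_alert_frac` | 0.158 | red share among false alerts |
| `cause_mix` | 0.323/0.187/0.184/0.146/0.083/0.077 | six-category false-alert cause mixture |
| `visit_interval_days` | 42 | scheduled visit grid |

`symptom_signature_strength` = 0.75 was chosen so the implied overall
detection ceiling (1 − blood_only_frac) × strength ≈ 0.41 brackets the
observed 39.1% sensitivity and the symptomatic ceiling 0.75 brackets
the observed 71.1%.  Event onset is uniform over follow-up (no hazard
shape is published).  Event categories are drawn from separate
laboratory-capable and symptomatic mixtures so that every symptomatic
event has a non-empty related-item set; baseline (non-alert) responses
never exceed grade 1, with grade-1 mass concentrated on fatigue and
general pain, the items that dominate observed alerts.  The signature
week's questionnaire is always completed — a patient experiencing the
symptoms answers — so the signature probability equals the achievable
detection probability exactly, and it is recorded per event as ground
truth; every injected false alert records its generating cause.

What the generator deliberately does **not** emulate: symptom
persistence after diagnosis (so prior-event alert labels are rare in
simulation), misses due to symptoms outside the instrument (expressible
via category maps but not generated by default), informative dropout,
pharmacological timing of specific toxicities, and within-patient
correlation of false alerts.  Passing recovery tests therefore show the
*pipeline* is unbiased under these generative assumptions, not that the
deployed instrument has any particular real-world performance.

Evaluation of a simulated cohort can exceed the generation-implied
ceiling slightly: a coincidental false alert containing a related item
may precede a diagnosis inside the window.  With default rates this
inflation is below ~5 percentage points and sits inside the 3-sigma
Monte-Carlo band used by the recovery tests (300-patient cohorts,
~16 000 questionnaires, a few seconds of runtime).

## Numerical and design notes

* Dates are calendar dates at day resolution for linkage and
  scheduling; `completed_at` carries time-of-day only for the
  working-hours logic.
* Determinism: one `numpy` Generator seeded from `SimulationParams.seed`
  drives all draws in a fixed order; equal parameters give
  byte-identical CSV bundles and reports.
* The cause-mixture default assigns 0.077 to tumour burden so the six
  proportions sum to exactly 1 (the published proportions, each rounded
  to three decimals, sum to 1.001; the unrounded share is 59/761 ≈
  0.0775).
* Domain types are frozen dataclasses with constructor-time invariant
  checks; questionnaire validation reports *all* violations at once,
  keyed by item and offending value, and is idempotent.
* The command-line interface is a thin layer over the library; no
  command mutates its inputs.

## Limitations

The evaluation reproduces the deployment study's own conventions,
including its mixed-unit confusion scheme — TN is not a count of
independent questionnaire outcomes, so Sp/NPV intervals understate
within-patient correlation.  Group-comparison statistics and the
mixed-effects regression of alert occurrence are out of scope, as are
portal/EHR integration and message delivery.
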