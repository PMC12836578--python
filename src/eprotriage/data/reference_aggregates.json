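{
  "description": "Aggregate tallies from the original single-center deployment cohort of the ImmuCare-PRO remote-monitoring system (136 melanoma patients on immune checkpoint inhibitors, 2018-2022). Patient-level data are not public; these published counts let the headline diagnostic metrics be recomputed offline.",
  "questionnaires_total": 5202,
  "score_counts": {"green": 4394, "orange": 661, "red": 122},
  "prior_irae_alert_questionnaires": 25,
  "alert_questionnaires": 783,
  "irae_grade2plus_total": 69,
  "irae_detected": 27,
  "irae_missed": 42,
  "detecting_questionnaires": 22,
  "irae_associated_questionnaires": 64,
  "irae_associated_questionnaires_symptomatic": 34,
  "green_followed_by_irae": 35,
  "false_alert_questionnaires": 761,
  "false_alert_causes": {
    "functional_nonspecific": 246,
    "previous_condition": 142,
    "independent_condition": 140,
    "input_error": 111,
    "overestimated_grade1": 63,
    "tumor_burden": 59
  },
  "miss_reasons": {
    "blood_disorder_no_clinical_impact": 31,
    "symptoms_not_in_questionnaire": 2,
    "questionnaire_not_completed": 1,
    "symptoms_not_reported": 8
  }
}
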