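"""Seeded synthetic-cohort generator.

Emulates the statistical structure of the deployment cohort: weekly
questionnaires over a lognormal follow-up (median 46 weeks, truncated
to 1-227), ~89% weekly completion, grade >=2 IrAEs in ~37% of patients
of which ~45% are blood-test-only disorders invisible to the
instrument, and per-questionnaire false alerts (~14.6%) drawn from the
six chart-review cause categories.

A symptomatic event leaves, with probability
``symptom_signature_strength``, a *symptom signature*: one or two of
its related items raised to grade 2 (grade 3 for grade-3/4 events) on
the questionnaire of the week preceding diagnosis.  That week's
questionnaire is always completed — a patient experiencing the symptoms
answers — so the signature probability is exactly the achievable
detection probability, recorded per event as ground truth.  Baseline
(non-alert) responses never exceed grade 1, so every alert is either a
signature or an injected false alert with a known cause.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .evaluation import FalseAlertCause, default_relatedness, diagnostic_metrics, wilson_ci
from .io import CohortBundle
from .model import (
    ITEM_IDS,
    IrAEEvent,
    Patient,
    Questionnaire,
    SymptomResponse,
    VisitSchedule,
)

__all__ = ["SimulationParams", "simulate_cohort", "ground_truth_metrics"]

# Mixture of event categories drawn for blood-test-only events
# (laboratory toxicities) vs symptomatic events (categories with a
# non-empty related-item set, so a signature is expressible).
_BLOOD_CATEGORY_WEIGHTS = {
    "thyroiditis": 0.50,
    "hyperlipasemia": 0.16,
    "hypophysitis": 0.13,
    "hepatitis": 0.16,
    "nephritis": 0.05,
}
_SYMPTOMATIC_CATEGORY_WEIGHTS = {
    "skin_toxicity": 0.21,
    "colitis_digestive": 0.24,
    "rheumatological": 0.11,
    "thyroiditis": 0.08,
    "hepatitis": 0.08,
    "hypophysitis": 0.05,
    "dry_syndrome": 0.08,
    "myositis": 0.05,
    "ophthalmological": 0.05,
    "interstitial_pneumonitis": 0.05,
}

# Baseline probability of a (non-alerting) grade-1 report, per item;
# fatigue and general pain dominate, as they dominate observed alerts.
_BASELINE_GRADE1 = {"fatigue": 0.25, "general_pain": 0.15}
_BASELINE_GRADE1_DEFAULT = 0.05

# Item weights for injected false alerts, skewed toward the
# functional/non-specific symptoms that dominate the false-alert pool.
_FALSE_ALERT_ITEM_WEIGHTS = {
    "fatigue": 0.28,
    "general_pain": 0.18,
    "shortness_of_breath": 0.10,
    "rash": 0.09,
    "decreased_appetite": 0.07,
    "numbness_tingling": 0.06,
    "headache": 0.06,
    "nausea_vomiting": 0.05,
    "diarrhea": 0.04,
    "blurred_vision": 0.04,
    "fever": 0.03,
}

_DEFAULT_CAUSE_MIX = {
    FalseAlertCause.FUNCTIONAL_NONSPECIFIC.value: 0.323,
    FalseAlertCause.PREVIOUS_CONDITION.value: 0.187,
    FalseAlertCause.INDEPENDENT_CONDITION.value: 0.184,
    FalseAlertCause.INPUT_ERROR.value: 0.146,
    FalseAlertCause.OVERESTIMATED_GRADE1.value: 0.083,
    FalseAlertCause.TUMOR_BURDEN.value: 0.077,
}


class ParamError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationParams:
    """Generator configuration; defaults are the deployment-cohort
    conditions (rates as published, sizes as deployed)."""

    n_patients: int = 136
    seed: int = 0
    followup_weeks_median: float = 46.0
    followup_weeks_sigma: float = 0.85
    followup_weeks_min: int = 1
    followup_weeks_max: int = 227
    adherence_prob: float = 0.89
    regimen_combo_frac: float = 0.096
    metastatic_frac: float = 0.338
    irae_patient_prob: float = 0.368
    extra_irae_mean: float = 0.38
    blood_only_frac: float = 0.449
    grade34_frac: float = 0.246
    symptom_signature_strength: float = 0.75
    false_alert_rate: float = 0.146
    red_false_alert_frac: float = 0.158
    cause_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CAUSE_MIX)
    )
    visit_interval_days: int = 42
    start_date: dt.date = dt.date(2020, 1, 6)
    enrollment_span_days: int = 730

    def validate(self) -> "SimulationParams":
        errs = []
        if self.n_patients < 0:
            errs.append("n_patients: must be >= 0")
        for name in (
            "adherence_prob", "regimen_combo_frac", "metastatic_frac",
            "irae_patient_prob", "blood_only_frac", "grade34_frac",
            "symptom_signature_strength", "false_alert_rate",
            "red_false_alert_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}: probability {v} outside [0, 1]")
        if abs(sum(self.cause_mix.values()) - 1.0) > 1e-9:
            errs.append("cause_mix: proportions must sum to 1")
        unknown = set(self.cause_mix) - {c.value for c in FalseAlertCause}
        if unknown:
            errs.append(f"cause_mix: unknown categories {sorted(unknown)}")
        if self.followup_weeks_min < 1 or self.followup_weeks_max < self.followup_weeks_min:
            errs.append("followup_weeks_min/max: invalid range")
        if self.visit_interval_days <= 0:
            errs.append("visit_interval_days: must be positive")
        if errs:
            raise ParamError("; ".join(errs))
        return self


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _followup_weeks(rng: np.random.Generator, p: SimulationParams) -> int:
    w = float(np.exp(rng.normal(np.log(p.followup_weeks_median), p.followup_weeks_sigma)))
    return int(np.clip(round(w), p.followup_weeks_min, p.followup_weeks_max))


def simulate_cohort(params: Optional[SimulationParams] = None) -> CohortBundle:
    """Generate a reproducible cohort bundle with ground truth.

    Identical parameters (including ``seed``) give identical bundles.
    Every questionnaire validates; diagnoses fall within follow-up;
    blood-only events leave no signature; each injected false alert
    records its generating cause.
    """
    p = (params or SimulationParams()).validate()
    rng = np.random.default_rng(p.seed)
    relatedness = default_relatedness()

    bundle = CohortBundle(ground_truth={}, causes={})
    cause_names = sorted(p.cause_mix)
    cause_probs = np.array([p.cause_mix[c] for c in cause_names], dtype=float)
    cause_probs = cause_probs / cause_probs.sum()
    fa_items = sorted(_FALSE_ALERT_ITEM_WEIGHTS)
    fa_probs = np.array([_FALSE_ALERT_ITEM_WEIGHTS[i] for i in fa_items], dtype=float)
    fa_probs = fa_probs / fa_probs.sum()

    for i in range(p.n_patients):
        pid = f"P{i:04d}"
        enrolled = p.start_date + dt.timedelta(
            days=int(rng.integers(0, p.enrollment_span_days))
        )
        weeks = _followup_weeks(rng, p)
        end = enrolled + dt.timedelta(days=7 * weeks)
        discontinued = end
        reason = ("scheduled_end", "progression", "transfer", "death", "refusal")[
            int(rng.choice(5, p=[0.49, 0.42, 0.03, 0.03, 0.03]))
        ]
        bundle.patients[pid] = Patient(
            patient_id=pid,
            sex="male" if rng.random() < 0.559 else "female",
            age_years=int(np.clip(round(rng.normal(57.5, 14.0)), 23, 85)),
            regimen=(
                "combo_ipi_nivo"
                if rng.random() < p.regimen_combo_frac
                else "anti_pd1_mono"
            ),
            indication="metastatic" if rng.random() < p.metastatic_frac else "adjuvant",
            cerebral_metastasis=bool(rng.random() < 0.10),
            enrolled_at=enrolled,
            discontinued_at=discontinued,
            discontinuation_reason=reason,
        )

        # visit grid; one visit beyond follow-up end so days-saved is
        # defined for late detections
        visits = []
        k = 1
        while True:
            d = enrolled + dt.timedelta(days=p.visit_interval_days * k)
            visits.append(d)
            if d > end:
                break
            k += 1
        bundle.visit_schedules[pid] = VisitSchedule(pid, tuple(visits))

        # IrAE events and their signature weeks
        signature_weeks: dict[int, list[tuple[str, int, frozenset[str]]]] = {}
        if rng.random() < p.irae_patient_prob:
            n_events = 1 + int(rng.poisson(p.extra_irae_mean))
            for j in range(n_events):
                irae_id = f"{pid}-E{j}"
                symptomatic = rng.random() >= p.blood_only_frac
                if symptomatic:
                    category = _weighted_choice(rng, _SYMPTOMATIC_CATEGORY_WEIGHTS)
                else:
                    category = _weighted_choice(rng, _BLOOD_CATEGORY_WEIGHTS)
                if rng.random() < p.grade34_frac:
                    grade = 4 if rng.random() < 0.3 else 3
                else:
                    grade = 2
                offset = int(rng.integers(7, max(8, 7 * weeks)))
                diagnosed = enrolled + dt.timedelta(days=offset)
                bundle.iraes.append(
                    IrAEEvent(
                        irae_id=irae_id,
                        patient_id=pid,
                        category=category,
                        ctcae_grade=grade,
                        diagnosed_at=diagnosed,
                        symptomatic=symptomatic,
                    )
                )
                detectable = False
                if symptomatic and rng.random() < p.symptom_signature_strength:
                    lead = int(rng.integers(0, 7))
                    w_sig = max(0, min(weeks - 1, (offset - lead) // 7))
                    related = relatedness.get(category, frozenset())
                    if related:
                        signature_weeks.setdefault(w_sig, []).append(
                            (irae_id, grade, related)
                        )
                        detectable = True
                bundle.ground_truth[irae_id] = detectable

        # weekly questionnaires
        for w in range(weeks):
            has_signature = w in signature_weeks
            completed = has_signature or (rng.random() < p.adherence_prob)
            if not completed:
                continue
            qid = f"{pid}-W{w:03d}"
            day = enrolled + dt.timedelta(days=7 * w)
            minute = int(rng.integers(0, 13 * 60))
            completed_at = dt.datetime.combine(
                day, dt.time(8, 0)
            ) + dt.timedelta(minutes=minute)

            grades = {
                item: int(
                    rng.random()
                    < _BASELINE_GRADE1.get(item, _BASELINE_GRADE1_DEFAULT)
                )
                for item in ITEM_IDS
            }
            if has_signature:
                for _, ev_grade, related in signature_weeks[w]:
                    pool = sorted(related)
                    n_lift = 1 if (len(pool) == 1 or rng.random() < 0.6) else 2
                    lifted = [
                        pool[idx]
                        for idx in rng.choice(len(pool), size=n_lift, replace=False)
                    ]
                    for idx, item in enumerate(lifted):
                        grades[item] = max(
                            grades[item], 3 if (ev_grade >= 3 and idx == 0) else 2
                        )
            elif rng.random() < p.false_alert_rate:
                cause = cause_names[int(rng.choice(len(cause_names), p=cause_probs))]
                bundle.causes[qid] = cause
                if rng.random() < p.red_false_alert_frac:
                    if rng.random() < 0.7:
                        item = fa_items[int(rng.choice(len(fa_items), p=fa_probs))]
                        grades[item] = 3
                    else:
                        for idx in rng.choice(len(fa_items), size=3, replace=False,
                                              p=fa_probs):
                            grades[fa_items[idx]] = 2
                else:
                    n_mod = 1 if rng.random() < 0.7 else 2
                    for idx in rng.choice(len(fa_items), size=n_mod, replace=False,
                                          p=fa_probs):
                        grades[fa_items[idx]] = 2

            bundle.questionnaires.append(
                Questionnaire(
                    questionnaire_id=qid,
                    patient_id=pid,
                    completed_at=completed_at,
                    responses=tuple(
                        SymptomResponse(item, grades[item]) for item in ITEM_IDS
                    ),
                )
            )

    return bundle.validate()


def ground_truth_metrics(bundle: CohortBundle) -> dict:
    """Achievable performance implied by the generation labels, for
    comparison against what the evaluation module estimates blind.

    Achievable sensitivity is the fraction of grade >=2 events whose
    signature actually landed on a completed questionnaire; achievable
    specificity treats exactly the injected false alerts as positives.
    """
    if bundle.ground_truth is None:
        raise ValueError("bundle has no ground truth (not simulated)")
    events = [e for e in bundle.iraes if e.ctcae_grade >= 2]
    n_all = len(events)
    n_sym = sum(1 for e in events if e.symptomatic)
    n_det = sum(1 for e in events if bundle.ground_truth.get(e.irae_id, False))
    n_quest = len(bundle.questionnaires)
    n_false = len(bundle.causes or {})

    def est(name, num, den):
        if den == 0:
            return {"name": name, "point": None, "numerator": num, "denominator": den}
        low, high = wilson_ci(num, den)
        return {
            "name": name,
            "point": num / den,
            "ci_low": low,
            "ci_high": high,
            "numerator": num,
            "denominator": den,
        }

    return {
        "achievable_sensitivity": est("achievable_sensitivity", n_det, n_all),
        "achievable_sensitivity_symptomatic": est(
            "achievable_sensitivity_symptomatic", n_det, n_sym
        ),
        "achievable_specificity": est(
            "achievable_specificity", n_quest - n_false, n_quest
        ),
    }
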