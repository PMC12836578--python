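"""Retrospective evaluation of alert-based IrAE detection.

A grade >=2 IrAE counts as *correctly detected* when it was preceded by
an alert-score questionnaire reporting at least one moderate/severe
symptom in the event's related-symptom set, completed no more than
``window_days`` before the diagnosis.  Among successive qualifying
alerts for one event only the earliest is the detector; later
qualifying alerts, and alerts whose related symptoms refer to an
already-diagnosed event, are excluded from the false-alert pool.

The confusion scheme is deliberately mixed-unit, matching the study
convention it evaluates: true positives and false negatives are counted
per IrAE *event*, false positives and true negatives per
*questionnaire*, with TN defined as green questionnaires minus the
missed events (each missed event is charged to one green questionnaire).
A pure questionnaire-level scheme is available for sensitivity
analyses.  All proportion confidence intervals are Wilson score
intervals by default (Clopper-Pearson exact optional).
"""

from __future__ import annotations

import datetime as dt
import enum
import json
import math
import statistics
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml
from statsmodels.stats.proportion import proportion_confint

from .model import IrAEEvent, Questionnaire, VisitSchedule
from .triage import Color, SeverityBucket, TriageScore

__all__ = [
    "MissReason",
    "QLabel",
    "FalseAlertCause",
    "DetectionLink",
    "QuestionnaireLabel",
    "ConfusionCounts",
    "MetricEstimate",
    "InconsistentCohortError",
    "default_relatedness",
    "link_detections",
    "confusion_counts",
    "wilson_ci",
    "diagnostic_metrics",
    "time_saved",
    "cause_summary",
    "cohort_report",
]


class MissReason(str, enum.Enum):
    BLOOD_DISORDER_NO_CLINICAL_IMPACT = "blood_disorder_no_clinical_impact"
    SYMPTOMS_NOT_IN_QUESTIONNAIRE = "symptoms_not_in_questionnaire"
    QUESTIONNAIRE_NOT_COMPLETED = "questionnaire_not_completed"
    SYMPTOMS_NOT_REPORTED = "symptoms_not_reported"


class QLabel(str, enum.Enum):
    GREEN = "green"
    ALERT_DETECTING = "alert_detecting"
    ALERT_FALSE = "alert_false"
    ALERT_PRIOR_IRAE = "alert_prior_irae"


class FalseAlertCause(str, enum.Enum):
    """The six chart-review cause categories for alerts with no
    associated grade >=2 IrAE."""

    FUNCTIONAL_NONSPECIFIC = "functional_nonspecific"
    PREVIOUS_CONDITION = "previous_condition"
    INDEPENDENT_CONDITION = "independent_condition"
    INPUT_ERROR = "input_error"
    OVERESTIMATED_GRADE1 = "overestimated_grade1"
    TUMOR_BURDEN = "tumor_burden"


@dataclass(frozen=True)
class DetectionLink:
    """Outcome of linkage for one grade >=2 IrAE: either the detecting
    questionnaire with its lead time, or a miss reason."""

    irae_ref: str
    detecting_questionnaire: Optional[str] = None
    detected_at: Optional[dt.date] = None
    lead_days: Optional[int] = None
    days_saved: Optional[int] = None
    miss_reason: Optional[MissReason] = None

    def __post_init__(self) -> None:
        if (self.detecting_questionnaire is None) == (self.miss_reason is None):
            raise ValueError(
                f"IrAE {self.irae_ref}: exactly one of detecting_questionnaire "
                "and miss_reason must be set"
            )
        if self.lead_days is not None and self.lead_days < 0:
            raise ValueError(f"IrAE {self.irae_ref}: negative lead_days")

    @property
    def detected(self) -> bool:
        return self.detecting_questionnaire is not None


@dataclass(frozen=True)
class QuestionnaireLabel:
    questionnaire_ref: str
    label: QLabel


class InconsistentCohortError(ValueError):
    """Raised when more events are missed than green questionnaires
    exist to charge them to (tn_quest would be negative)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Mixed-unit confusion tally: TP/FN per IrAE event, FP/TN per
    questionnaire, TN = green questionnaires - missed events.

    ``tn_mode="greens"`` switches to the pure questionnaire-level
    alternative where every green questionnaire is a true negative.
    """

    tp_irae: int
    fn_irae: int
    fp_quest: int
    green_quest: int
    prior_quest: int = 0
    tn_mode: str = "greens_minus_fn"

    def __post_init__(self) -> None:
        for name in ("tp_irae", "fn_irae", "fp_quest", "green_quest", "prior_quest"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn_mode not in ("greens_minus_fn", "greens"):
            raise ValueError(f"unknown tn_mode {self.tn_mode!r}")
        if self.tn_quest < 0:
            raise InconsistentCohortError(
                f"{self.fn_irae} missed events exceed {self.green_quest} green questionnaires"
            )

    @property
    def tn_quest(self) -> int:
        if self.tn_mode == "greens":
            return self.green_quest
        return self.green_quest - self.fn_irae


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its binomial confidence interval.  When the
    denominator is zero the metric is undefined: ``point`` and both
    bounds are None rather than fabricated."""

    name: str
    numerator: int
    denominator: int
    point: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    level: float = 0.95

    @property
    def defined(self) -> bool:
        return self.point is not None


_DEFAULT_RELATEDNESS: Optional[dict[str, frozenset[str]]] = None


def default_relatedness() -> dict[str, frozenset[str]]:
    """Category -> related questionnaire items, from the packaged
    configuration file."""
    global _DEFAULT_RELATEDNESS
    if _DEFAULT_RELATEDNESS is None:
        text = resources.files("eprotriage.data").joinpath("relatedness.yaml").read_text()
        raw = yaml.safe_load(text)
        _DEFAULT_RELATEDNESS = {k: frozenset(v or ()) for k, v in raw.items()}
    return dict(_DEFAULT_RELATEDNESS)


def _related_items(
    irae: IrAEEvent, relatedness: Mapping[str, frozenset[str]]
) -> frozenset[str]:
    if irae.related_items:
        return frozenset(irae.related_items)
    if not irae.symptomatic:
        # a lab-only disorder without clinical impact has no related
        # symptoms, whatever its category's default map says
        return frozenset()
    return frozenset(relatedness.get(irae.category, frozenset()))


def _flagged_items(q: Questionnaire) -> frozenset[str]:
    """Items reported at grade >=2 (moderate or severe)."""
    return frozenset(r.item_id for r in q.responses if r.grade >= 2)


def link_detections(
    questionnaires: Sequence[tuple[Questionnaire, TriageScore]],
    iraes: Sequence[IrAEEvent],
    window_days: int = 30,
    relatedness: Optional[Mapping[str, frozenset[str]]] = None,
) -> tuple[list[DetectionLink], list[QuestionnaireLabel]]:
    """Link alert questionnaires to grade >=2 IrAEs.

    Parameters
    ----------
    questionnaires
        Scored questionnaires, as ``(questionnaire, triage_score)``.
    iraes
        IrAE registry events; grade <2 events are ignored.
    window_days
        Maximum days between a qualifying alert and the diagnosis.
    relatedness
        Category -> item-set fallback used when an event carries no
        explicit ``related_items``; defaults to the packaged map.

    Returns one :class:`DetectionLink` per grade >=2 event and one
    :class:`QuestionnaireLabel` per questionnaire.  A questionnaire
    qualifies for an event when it is an alert, completed on or before
    the diagnosis date and at most ``window_days`` earlier, and reports
    a moderate/severe grade on a related item.  The earliest qualifying
    alert is the detector (ties on the same day broken by questionnaire
    id); other qualifying alerts and related alerts up to
    ``window_days`` *after* the diagnosis are labelled
    ``alert_prior_irae``.  One questionnaire may detect several
    simultaneous events.
    """
    relatedness = dict(relatedness) if relatedness is not None else default_relatedness()
    by_patient: dict[str, list[tuple[Questionnaire, TriageScore]]] = {}
    for q, s in questionnaires:
        by_patient.setdefault(q.patient_id, []).append((q, s))

    links: list[DetectionLink] = []
    detecting: set[str] = set()
    prior: set[str] = set()

    for irae in iraes:
        if irae.ctcae_grade < 2:
            continue
        related = _related_items(irae, relatedness)
        patient_qs = by_patient.get(irae.patient_id, [])
        qualifying: list[tuple[dt.date, str]] = []
        for q, s in patient_qs:
            if not s.color.is_alert:
                continue
            q_day = q.completed_at.date()
            lead = (irae.diagnosed_at - q_day).days
            if 0 <= lead <= window_days and (_flagged_items(q) & related):
                qualifying.append((q_day, q.questionnaire_id))
            elif -window_days <= lead < 0 and (_flagged_items(q) & related):
                # related alert after diagnosis: symptom persistence of a
                # known event, excluded from the false-alert pool
                prior.add(q.questionnaire_id)
        if qualifying:
            qualifying.sort()
            day, qid = qualifying[0]
            detecting.add(qid)
            for _, later_qid in qualifying[1:]:
                if later_qid != qid:
                    prior.add(later_qid)
            links.append(
                DetectionLink(
                    irae_ref=irae.irae_id,
                    detecting_questionnaire=qid,
                    detected_at=day,
                    lead_days=(irae.diagnosed_at - day).days,
                )
            )
        else:
            links.append(
                DetectionLink(
                    irae_ref=irae.irae_id,
                    miss_reason=_miss_reason(irae, related, patient_qs, window_days),
                )
            )

    prior -= detecting
    labels: list[QuestionnaireLabel] = []
    for q, s in questionnaires:
        if not s.color.is_alert:
            label = QLabel.GREEN
        elif q.questionnaire_id in detecting:
            label = QLabel.ALERT_DETECTING
        elif q.questionnaire_id in prior:
            label = QLabel.ALERT_PRIOR_IRAE
        else:
            label = QLabel.ALERT_FALSE
        labels.append(QuestionnaireLabel(q.questionnaire_id, label))
    return links, labels


def _miss_reason(
    irae: IrAEEvent,
    related: frozenset[str],
    patient_qs: Sequence[tuple[Questionnaire, TriageScore]],
    window_days: int,
) -> MissReason:
    # Assignment order: laboratory-only event, then no questionnaire in
    # the pre-diagnosis window, then symptoms outside the instrument,
    # else symptoms present in the instrument but not reported.
    if not irae.symptomatic:
        return MissReason.BLOOD_DISORDER_NO_CLINICAL_IMPACT
    in_window = any(
        0 <= (irae.diagnosed_at - q.completed_at.date()).days <= window_days
        for q, _ in patient_qs
    )
    if not in_window:
        return MissReason.QUESTIONNAIRE_NOT_COMPLETED
    if not related:
        return MissReason.SYMPTOMS_NOT_IN_QUESTIONNAIRE
    return MissReason.SYMPTOMS_NOT_REPORTED


def confusion_counts(
    links: Sequence[DetectionLink],
    labels: Sequence[QuestionnaireLabel],
    symptomatic_only: bool = False,
    scheme: str = "mixed",
) -> ConfusionCounts:
    """Build the confusion tally from linkage output.

    ``symptomatic_only`` drops blood-test-only events (miss reason
    ``blood_disorder_no_clinical_impact``) from the event-level counts.
    ``scheme="mixed"`` (default) sets TN = greens - missed events;
    ``scheme="questionnaire"`` counts TP as detecting questionnaires and
    TN as all greens, a pure questionnaire-level alternative.
    """
    if scheme not in ("mixed", "questionnaire"):
        raise ValueError(f"unknown scheme {scheme!r}")
    kept = [
        ln
        for ln in links
        if not (
            symptomatic_only
            and ln.miss_reason is MissReason.BLOOD_DISORDER_NO_CLINICAL_IMPACT
        )
    ]
    tp = sum(1 for ln in kept if ln.detected)
    fn = sum(1 for ln in kept if not ln.detected)
    fp = sum(1 for lb in labels if lb.label is QLabel.ALERT_FALSE)
    green = sum(1 for lb in labels if lb.label is QLabel.GREEN)
    prior = sum(1 for lb in labels if lb.label is QLabel.ALERT_PRIOR_IRAE)
    if scheme == "questionnaire":
        tp = len({ln.detecting_questionnaire for ln in kept if ln.detected})
        return ConfusionCounts(tp, fn, fp, green, prior, tn_mode="greens")
    return ConfusionCounts(tp, fn, fp, green, prior)


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    low, high = proportion_confint(successes, trials, alpha=1 - level, method="wilson")
    # the closed form hits the boundary exactly at k=0 / k=n
    if successes == 0:
        low = 0.0
    if successes == trials:
        high = 1.0
    return float(low), float(high)


def _estimate(
    name: str, num: int, den: int, level: float, ci_method: str
) -> MetricEstimate:
    if den == 0:
        return MetricEstimate(name, num, den, None, None, None, level)
    method = {"wilson": "wilson", "exact": "beta"}[ci_method]
    low, high = proportion_confint(num, den, alpha=1 - level, method=method)
    return MetricEstimate(name, num, den, num / den, float(low), float(high), level)


def diagnostic_metrics(
    cc: ConfusionCounts, level: float = 0.95, ci_method: str = "wilson"
) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity, PPV and NPV with binomial CIs.

    Each metric gets its interval on its own numerator/denominator;
    zero-denominator metrics come back undefined rather than invented.
    """
    tp, fn, fp, tn = cc.tp_irae, cc.fn_irae, cc.fp_quest, cc.tn_quest
    return {
        "sensitivity": _estimate("sensitivity", tp, tp + fn, level, ci_method),
        "specificity": _estimate("specificity", tn, tn + fp, level, ci_method),
        "ppv": _estimate("ppv", tp, tp + fp, level, ci_method),
        "npv": _estimate("npv", tn, tn + fn, level, ci_method),
    }


def time_saved(
    link: DetectionLink, schedule: VisitSchedule, diagnosed_at: dt.date
) -> Optional[int]:
    """Days saved by alert-triggered management relative to waiting for
    the next scheduled visit: (first visit strictly after the detecting
    questionnaire) - diagnosis date, floored at zero.  None when no
    future visit exists (excluded from summaries)."""
    if not link.detected:
        raise ValueError(f"IrAE {link.irae_ref} was not detected")
    nxt = schedule.next_visit_after(link.detected_at)
    if nxt is None:
        return None
    return max(0, (nxt - diagnosed_at).days)


def cause_summary(
    labels: Sequence[QuestionnaireLabel],
    causes: Mapping[str, FalseAlertCause],
) -> dict[str, dict[str, float]]:
    """Count and proportion per false-alert cause category.

    Every questionnaire labelled ``alert_false`` must carry a cause
    annotation (chart review, or simulator ground truth); missing
    annotations are reported by questionnaire reference.
    """
    false_refs = [lb.questionnaire_ref for lb in labels if lb.label is QLabel.ALERT_FALSE]
    missing = [ref for ref in false_refs if ref not in causes]
    if missing:
        raise KeyError(
            f"missing false-alert cause annotation for questionnaires: {sorted(missing)}"
        )
    total = len(false_refs)
    out: dict[str, dict[str, float]] = {}
    for cause in FalseAlertCause:
        n = sum(1 for ref in false_refs if FalseAlertCause(causes[ref]) is cause)
        if total:
            out[cause.value] = {"count": n, "proportion": n / total}
    return out


def _summary_stats(values: Sequence[int]) -> dict[str, float]:
    if not values:
        return {"n": 0}
    return {
        "n": len(values),
        "mean": float(statistics.fmean(values)),
        "median": float(statistics.median(values)),
        "min": float(min(values)),
        "max": float(max(values)),
    }


def cohort_report(bundle, policy=None, window_days: int = 30) -> dict:
    """Full retrospective evaluation of a cohort bundle.

    Scores every questionnaire under ``policy``, links alerts to grade
    >=2 events, and returns a nested dict: score distribution and alert
    rate, questionnaire labels, detection/miss tallies per category and
    miss reason, diagnostic metrics for all events and for symptomatic
    events only, false-alert causes (when annotations exist), and
    lead-time / days-saved summaries.
    """
    from .triage import ScoringPolicy, score_questionnaire  # local to avoid cycle

    policy = policy or ScoringPolicy.default()
    scored = [(q, score_questionnaire(q, policy)) for q in bundle.questionnaires]
    n_total = len(scored)
    score_counts = {c.value: 0 for c in Color}
    for _, s in scored:
        score_counts[s.color.value] += 1

    links, labels = link_detections(
        scored, bundle.iraes, window_days=window_days
    )
    label_counts = {lb.value: 0 for lb in QLabel}
    for lab in labels:
        label_counts[lab.label.value] += 1
    n_alert = label_counts["alert_detecting"] + label_counts["alert_false"]

    irae_by_id = {e.irae_id: e for e in bundle.iraes}
    detected_by_cat: dict[str, int] = {}
    missed_by_cat: dict[str, int] = {}
    miss_reasons = {r.value: 0 for r in MissReason}
    lead_days: list[int] = []
    saved: list[int] = []
    for ln in links:
        cat = irae_by_id[ln.irae_ref].category
        if ln.detected:
            detected_by_cat[cat] = detected_by_cat.get(cat, 0) + 1
            lead_days.append(ln.lead_days)
            sched = bundle.visit_schedules.get(irae_by_id[ln.irae_ref].patient_id)
            if sched is not None:
                ds = time_saved(ln, sched, irae_by_id[ln.irae_ref].diagnosed_at)
                if ds is not None:
                    saved.append(ds)
        else:
            missed_by_cat[cat] = missed_by_cat.get(cat, 0) + 1
            miss_reasons[ln.miss_reason.value] += 1

    report = {
        "n_questionnaires": n_total,
        "score_counts": score_counts,
        "alert_rate": (n_alert / n_total) if n_total else None,
        "label_counts": label_counts,
        "n_irae_grade2plus": len(links),
        "n_detected": sum(1 for ln in links if ln.detected),
        "n_missed": sum(1 for ln in links if not ln.detected),
        "detected_by_category": dict(sorted(detected_by_cat.items())),
        "missed_by_category": dict(sorted(missed_by_cat.items())),
        "miss_reasons": miss_reasons,
        "lead_days": _summary_stats(lead_days),
        "days_saved": _summary_stats(saved),
    }
    for key, sympt in (("metrics_all", False), ("metrics_symptomatic", True)):
        if links or labels:
            cc = confusion_counts(links, labels, symptomatic_only=sympt)
            report[key] = {
                name: {
                    "point": m.point,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "numerator": m.numerator,
                    "denominator": m.denominator,
                }
                for name, m in diagnostic_metrics(cc).items()
            }
        else:
            report[key] = {}
    if bundle.causes is not None and (links or labels):
        report["false_alert_causes"] = cause_summary(labels, bundle.causes)
    return report
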