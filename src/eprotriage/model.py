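"""Domain types for ePRO-based remote monitoring of patients on immune
checkpoint inhibitors.

The unit of data collection is a weekly 11-item symptom questionnaire
graded 0..3 (0..4 for the two gastro-intestinal items), modelled on
CTCAE v5 / PRO-CTCAE severity scales.  Immune-related adverse events
(IrAEs) are recorded separately in a registry with their CTCAE grade,
diagnosis date and the set of questionnaire items that count as
"related symptoms" for detection purposes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ITEM_IDS",
    "IRAE_CATEGORIES",
    "SymptomItem",
    "SymptomResponse",
    "Questionnaire",
    "Patient",
    "IrAEEvent",
    "VisitSchedule",
    "QuestionnaireValidationError",
    "standard_item_set",
    "validate_questionnaire",
]

#: Canonical identifiers of the 11 questionnaire items, in display order.
ITEM_IDS: tuple[str, ...] = (
    "fever",
    "fatigue",
    "headache",
    "shortness_of_breath",
    "nausea_vomiting",
    "rash",
    "diarrhea",
    "decreased_appetite",
    "numbness_tingling",
    "general_pain",
    "blurred_vision",
)

_ITEM_LABELS: dict[str, str] = {
    "fever": "Fever",
    "fatigue": "Fatigue",
    "headache": "Headache",
    "shortness_of_breath": "Shortness of breath",
    "nausea_vomiting": "Nausea / vomiting",
    "rash": "Rash",
    "diarrhea": "Diarrhea",
    "decreased_appetite": "Decreased appetite",
    "numbness_tingling": "Numbness / tingling",
    "general_pain": "General pain",
    "blurred_vision": "Blurred vision",
}

# Items whose CTCAE analogue extends to grade 4 in outpatient self-report.
_GRADE4_ITEMS = frozenset({"nausea_vomiting", "diarrhea"})

#: IrAE registry categories.
IRAE_CATEGORIES: tuple[str, ...] = (
    "thyroiditis",
    "colitis_digestive",
    "hepatitis",
    "skin_toxicity",
    "hypophysitis",
    "hyperlipasemia",
    "rheumatological",
    "dry_syndrome",
    "myositis",
    "ophthalmological",
    "nephritis",
    "mixed_connective_tissue",
    "interstitial_pneumonitis",
    "other",
)

SEXES = ("male", "female")
REGIMENS = ("combo_ipi_nivo", "anti_pd1_mono")
INDICATIONS = ("adjuvant", "metastatic")
DISCONTINUATION_REASONS = (
    "scheduled_end",
    "progression",
    "transfer",
    "death",
    "refusal",
)


@dataclass(frozen=True)
class SymptomItem:
    """One questionnaire item: an identifier, display label, and the
    highest grade its response scale offers (3 or 4)."""

    item_id: str
    label: str
    max_grade: int

    def __post_init__(self) -> None:
        if self.max_grade not in (3, 4):
            raise ValueError(
                f"max_grade must be 3 or 4, got {self.max_grade} for {self.item_id!r}"
            )


@dataclass(frozen=True)
class SymptomResponse:
    """A single graded answer: item identifier plus severity grade."""

    item_id: str
    grade: int


@dataclass(frozen=True)
class Questionnaire:
    """One patient-week of responses; the unit of triage scoring.

    ``completed_at`` carries time-of-day because alert handling depends
    on working hours; all other linkage happens at day resolution.
    """

    questionnaire_id: str
    patient_id: str
    completed_at: dt.datetime
    responses: tuple[SymptomResponse, ...]
    free_text: Optional[str] = None
    callback_requested: bool = False

    def grade_of(self, item_id: str) -> int:
        for r in self.responses:
            if r.item_id == item_id:
                return r.grade
        raise KeyError(item_id)

    def grades(self) -> dict[str, int]:
        return {r.item_id: r.grade for r in self.responses}


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str
    age_years: int
    regimen: str
    indication: str
    cerebral_metastasis: bool
    enrolled_at: dt.date
    discontinued_at: Optional[dt.date] = None
    discontinuation_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.discontinued_at is not None and self.discontinued_at < self.enrolled_at:
            raise ValueError(
                f"patient {self.patient_id}: discontinued_at {self.discontinued_at} "
                f"precedes enrolled_at {self.enrolled_at}"
            )


@dataclass(frozen=True)
class IrAEEvent:
    """A CTCAE-graded immune-related adverse event.

    ``symptomatic=False`` marks a blood-test disorder without clinical
    impact — structurally invisible to a symptom questionnaire.
    ``related_items`` is the set of questionnaire items whose report
    counts as "related symptoms" when linking alerts to this event; when
    empty, a category-level default map is consulted at evaluation time.
    """

    irae_id: str
    patient_id: str
    category: str
    ctcae_grade: int
    diagnosed_at: dt.date
    symptomatic: bool
    related_items: frozenset[str] = frozenset()
    managed_at: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if not 1 <= self.ctcae_grade <= 4:
            raise ValueError(
                f"IrAE {self.irae_id}: ctcae_grade must be in 1..4, got {self.ctcae_grade}"
            )
        if self.category not in IRAE_CATEGORIES:
            raise ValueError(f"IrAE {self.irae_id}: unknown category {self.category!r}")


@dataclass(frozen=True)
class VisitSchedule:
    """Scheduled clinic visit dates for one patient, strictly increasing.

    Nominal inter-visit gaps are 3-6 weeks; the constructor enforces
    ordering only, since real schedules contain ad-hoc visits.
    """

    patient_id: str
    visit_dates: tuple[dt.date, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.visit_dates, self.visit_dates[1:]):
            if b <= a:
                raise ValueError(
                    f"visit schedule for {self.patient_id}: dates not strictly increasing "
                    f"({a} then {b})"
                )

    def next_visit_after(self, day: dt.date) -> Optional[dt.date]:
        """First scheduled visit strictly after ``day``, or None."""
        for d in self.visit_dates:
            if d > day:
                return d
        return None


def standard_item_set(
    ceilings: Optional[Mapping[str, int]] = None,
) -> list[SymptomItem]:
    """The 11 canonical items in stable order.

    Default grade ceiling is 3 everywhere except nausea/vomiting and
    diarrhea (ceiling 4).  ``ceilings`` overrides per item; triage only
    distinguishes grade <=1 / =2 / >=3, so the ceiling choice never
    changes a score — it only bounds validation.
    """
    ceilings = dict(ceilings or {})
    items = []
    for item_id in ITEM_IDS:
        default = 4 if item_id in _GRADE4_ITEMS else 3
        items.append(
            SymptomItem(
                item_id=item_id,
                label=_ITEM_LABELS[item_id],
                max_grade=ceilings.get(item_id, default),
            )
        )
    return items


class QuestionnaireValidationError(ValueError):
    """Raised when a questionnaire violates the item-set contract.

    ``errors`` is a list of ``(code, item_id, value)`` triples, one per
    violation, so callers can report every problem at once.
    """

    def __init__(self, questionnaire_id: str, errors: list[tuple[str, str, object]]):
        self.questionnaire_id = questionnaire_id
        self.errors = errors
        detail = "; ".join(
            f"{code}: item {item_id!r} value {value!r}" for code, item_id, value in errors
        )
        super().__init__(f"questionnaire {questionnaire_id!r} invalid — {detail}")


def validate_questionnaire(
    q: Questionnaire, item_set: Optional[Sequence[SymptomItem]] = None
) -> Questionnaire:
    """Check that ``q`` answers every item of ``item_set`` exactly once
    with an in-range grade; return ``q`` unchanged if so.

    Idempotent: validating an already-valid questionnaire is a no-op.
    Raises :class:`QuestionnaireValidationError` listing every violation
    (missing_item / duplicate_item / unknown_item / out_of_range_grade).
    """
    items = {it.item_id: it for it in (item_set or standard_item_set())}
    errors: list[tuple[str, str, object]] = []

    seen: dict[str, int] = {}
    for r in q.responses:
        if r.item_id not in items:
            errors.append(("unknown_item", r.item_id, r.grade))
            continue
        if r.item_id in seen:
            errors.append(("duplicate_item", r.item_id, r.grade))
            continue
        seen[r.item_id] = r.grade
        it = items[r.item_id]
        if not 0 <= r.grade <= it.max_grade:
            errors.append(("out_of_range_grade", r.item_id, r.grade))
    for item_id in items:
        if item_id not in seen:
            errors.append(("missing_item", item_id, None))

    if errors:
        raise QuestionnaireValidationError(q.questionnaire_id, errors)
    return q
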