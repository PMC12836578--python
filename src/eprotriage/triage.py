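"""Triage scoring and alert workflow.

Each graded response is bucketed as absent/slight (grade 0-1), moderate
(grade 2) or severe (grade 3-4).  The questionnaire colour is:

* **green**  — no moderate and no severe symptom;
* **orange** — one or two moderate symptoms, no severe one;
* **red**    — at least one severe symptom, or three or more moderate.

Orange and red scores are "alert scores": orange requires a nurse call
within 24-48 h of effective receipt, red an immediate call.  Alerts are
handled during working hours (09:00-16:30); a questionnaire arriving
outside that window is treated as received at the next opening.

A :class:`ScoringPolicy` can escalate individual items (e.g. force any
grade-2 diarrhea to the severe bucket so it alone turns the score red),
a variant proposed to catch potentially severe immune-induced colitis
earlier.  Overrides act at the bucketing step so the moderate/severe
counts stay meaningful.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml

from .model import Questionnaire, SymptomItem, standard_item_set

__all__ = [
    "Color",
    "SeverityBucket",
    "TriageScore",
    "ScoringPolicy",
    "WorkingHours",
    "Alert",
    "HANDLING_MODES",
    "bucket",
    "score_questionnaire",
    "effective_receipt",
    "raise_alert",
    "reminder_schedule",
    "monthly_call_schedule",
]


class Color(str, enum.Enum):
    GREEN = "green"
    ORANGE = "orange"
    RED = "red"

    @property
    def rank(self) -> int:
        return {"green": 0, "orange": 1, "red": 2}[self.value]

    @property
    def is_alert(self) -> bool:
        return self is not Color.GREEN


class SeverityBucket(str, enum.Enum):
    ABSENT_SLIGHT = "absent_slight"
    MODERATE = "moderate"
    SEVERE = "severe"


HANDLING_MODES = (
    "nurse_only",
    "teleconsultation",
    "rapid_admission",
    "gp_visit",
    "emergency_room",
    "next_scheduled_visit",
)


@dataclass(frozen=True)
class TriageScore:
    color: Color
    n_moderate: int
    n_severe: int


@dataclass(frozen=True)
class ScoringPolicy:
    """Scoring configuration: the item set in force and per-item
    escalation overrides.

    ``escalation_overrides`` maps item_id -> minimum grade that is
    force-bucketed severe.  Empty overrides reproduce the deployed
    scoring rule exactly.
    """

    escalation_overrides: Mapping[str, int] = field(default_factory=dict)
    item_set: tuple[SymptomItem, ...] = field(
        default_factory=lambda: tuple(standard_item_set())
    )

    def __post_init__(self) -> None:
        known = {it.item_id for it in self.item_set}
        for item_id in self.escalation_overrides:
            if item_id not in known:
                raise ValueError(f"escalation override for unknown item {item_id!r}")

    @classmethod
    def default(cls) -> "ScoringPolicy":
        return cls()

    @classmethod
    def from_yaml(cls, path) -> "ScoringPolicy":
        """Load a policy file with optional ``item_ceilings`` and
        ``escalation_overrides`` mappings."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        items = tuple(standard_item_set(cfg.get("item_ceilings")))
        return cls(
            escalation_overrides=dict(cfg.get("escalation_overrides") or {}),
            item_set=items,
        )


@dataclass(frozen=True)
class WorkingHours:
    """Daily alert-handling window; weekends are working days unless
    ``weekends_off`` is set (the deployed workflow states no weekend
    rule)."""

    opens: dt.time = dt.time(9, 0)
    closes: dt.time = dt.time(16, 30)
    weekends_off: bool = False

    def is_open(self, ts: dt.datetime) -> bool:
        if self.weekends_off and ts.weekday() >= 5:
            return False
        return self.opens <= ts.time() <= self.closes


@dataclass(frozen=True)
class Alert:
    questionnaire_ref: str
    color: Color
    raised_at: dt.datetime
    respond_by_earliest: dt.datetime
    respond_by_latest: dt.datetime
    handling: Optional[str] = None

    def __post_init__(self) -> None:
        if self.respond_by_earliest > self.respond_by_latest:
            raise ValueError("respond_by_earliest after respond_by_latest")
        if self.handling is not None and self.handling not in HANDLING_MODES:
            raise ValueError(f"unknown handling mode {self.handling!r}")


def bucket(
    grade: int, item_id: str, policy: Optional[ScoringPolicy] = None
) -> SeverityBucket:
    """Map one graded response to its severity bucket under ``policy``."""
    policy = policy or ScoringPolicy.default()
    if item_id not in {it.item_id for it in policy.item_set}:
        raise KeyError(f"item {item_id!r} not in the policy's item set")
    override = policy.escalation_overrides.get(item_id)
    if override is not None and grade >= override:
        return SeverityBucket.SEVERE
    if grade >= 3:
        return SeverityBucket.SEVERE
    if grade == 2:
        return SeverityBucket.MODERATE
    return SeverityBucket.ABSENT_SLIGHT


def score_questionnaire(
    q: Questionnaire, policy: Optional[ScoringPolicy] = None
) -> TriageScore:
    """Compute the green/orange/red triage score of a validated
    questionnaire.  Deterministic; the three colour regions partition
    the (moderate count, severe count) plane."""
    policy = policy or ScoringPolicy.default()
    m = s = 0
    for r in q.responses:
        b = bucket(r.grade, r.item_id, policy)
        if b is SeverityBucket.MODERATE:
            m += 1
        elif b is SeverityBucket.SEVERE:
            s += 1
    if s >= 1 or m >= 3:
        color = Color.RED
    elif m >= 1:
        color = Color.ORANGE
    else:
        color = Color.GREEN
    return TriageScore(color=color, n_moderate=m, n_severe=s)


def effective_receipt(ts: dt.datetime, hours: Optional[WorkingHours] = None) -> dt.datetime:
    """Timestamp at which an alert is effectively taken into account:
    ``ts`` itself inside working hours, else the next opening."""
    hours = hours or WorkingHours()
    if hours.is_open(ts):
        return ts
    day = ts.date()
    if ts.time() > hours.closes:
        day = day + dt.timedelta(days=1)
    while hours.weekends_off and day.weekday() >= 5:
        day = day + dt.timedelta(days=1)
    return dt.datetime.combine(day, hours.opens)


def raise_alert(
    score: TriageScore,
    q_ref: str,
    received_at: dt.datetime,
    hours: Optional[WorkingHours] = None,
) -> Optional[Alert]:
    """Turn a triage score into an alert with its response window.

    Green returns None.  Orange: call within [24 h, 48 h] of effective
    receipt.  Red: immediate — both window bounds equal effective
    receipt.
    """
    if score.color is Color.GREEN:
        return None
    eff = effective_receipt(received_at, hours)
    if score.color is Color.RED:
        earliest = latest = eff
    else:
        earliest = eff + dt.timedelta(hours=24)
        latest = eff + dt.timedelta(hours=48)
    return Alert(
        questionnaire_ref=q_ref,
        color=score.color,
        raised_at=eff,
        respond_by_earliest=earliest,
        respond_by_latest=latest,
    )


def reminder_schedule(
    invited_at: dt.datetime,
    completed_at: Optional[dt.datetime] = None,
    *,
    until: Optional[dt.datetime] = None,
    period_days: int = 7,
    max_reminders: Optional[int] = None,
) -> list[dt.datetime]:
    """Reminder timestamps for one questionnaire invitation.

    A reminder fires every ``period_days`` after the invitation while
    the questionnaire remains uncompleted, stopping at completion, at
    ``until`` (e.g. monitoring discontinuation), or after
    ``max_reminders``, whichever comes first.
    """
    if period_days <= 0:
        raise ValueError("period_days must be positive")
    bounds = [b for b in (completed_at, until) if b is not None]
    stop = min(bounds) if bounds else None
    if stop is None and max_reminders is None:
        return []  # open-ended invitation with no bound: nothing to enumerate
    reminders: list[dt.datetime] = []
    k = 1
    while max_reminders is None or len(reminders) < max_reminders:
        t = invited_at + dt.timedelta(days=period_days * k)
        if stop is not None and t >= stop:
            break
        reminders.append(t)
        k += 1
    return reminders


def monthly_call_schedule(enrolled_at: dt.date, end_at: dt.date) -> list[dt.date]:
    """Systematic nurse-call dates: one per 28-day period from
    enrollment, truncated at ``end_at`` (a fixed 28-day grid rather
    than calendar months, for determinism)."""
    if end_at < enrolled_at:
        raise ValueError("end_at precedes enrolled_at")
    calls = []
    k = 1
    while True:
        d = enrolled_at + dt.timedelta(days=28 * k)
        if d > end_at:
            break
        calls.append(d)
        k += 1
    return calls
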