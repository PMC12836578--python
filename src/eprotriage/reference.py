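"""Published aggregate counts from the original deployment cohort.

Patient-level data from the deployment study are not public, so full
per-event tables cannot be rebuilt.  What *is* published — score
tallies, detection/miss counts, false-alert cause counts — suffices to
recompute every headline quantity: the mixed-unit confusion counts, the
four diagnostic metrics with Wilson intervals (all events and
symptomatic-only), the alert rate and the bookkeeping shares.  This
module exposes those counts and the derived quantities.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

from .evaluation import ConfusionCounts, MetricEstimate, diagnostic_metrics, wilson_ci

__all__ = [
    "reference_aggregates",
    "reference_confusion_counts",
    "reference_headline",
]

_CACHE: Optional[dict] = None


def reference_aggregates() -> dict:
    """The packaged aggregate tallies (counts only, no derived rates)."""
    global _CACHE
    if _CACHE is None:
        text = (
            resources.files("eprotriage.data")
            .joinpath("reference_aggregates.json")
            .read_text()
        )
        _CACHE = json.loads(text)
    return dict(_CACHE)


def reference_confusion_counts(symptomatic_only: bool = False) -> ConfusionCounts:
    """Mixed-unit confusion counts rebuilt from the published tallies.

    ``symptomatic_only`` removes the blood-test-only events (all of
    which were missed) from the event-level counts.
    """
    agg = reference_aggregates()
    tp = agg["irae_detected"]
    fn = agg["irae_missed"]
    if symptomatic_only:
        fn -= agg["miss_reasons"]["blood_disorder_no_clinical_impact"]
    return ConfusionCounts(
        tp_irae=tp,
        fn_irae=fn,
        fp_quest=agg["false_alert_questionnaires"],
        green_quest=agg["score_counts"]["green"],
        prior_quest=agg["prior_irae_alert_questionnaires"],
    )


def reference_headline(level: float = 0.95) -> dict:
    """All headline quantities recomputed from the published counts.

    Fractions are returned in [0, 1]; multiply by 100 for the percent
    scale of the published tables.
    """
    agg = reference_aggregates()
    cc_all = reference_confusion_counts(symptomatic_only=False)
    cc_sym = reference_confusion_counts(symptomatic_only=True)
    m_all = diagnostic_metrics(cc_all, level=level)
    m_sym = diagnostic_metrics(cc_sym, level=level)

    n_quest = agg["questionnaires_total"]
    n_alert = agg["alert_questionnaires"]
    causes = agg["false_alert_causes"]
    n_false = agg["false_alert_questionnaires"]
    se_low, se_high = wilson_ci(cc_all.tp_irae, cc_all.tp_irae + cc_all.fn_irae, level)

    return {
        "confusion_all": cc_all,
        "confusion_symptomatic": cc_sym,
        "metrics_all": m_all,
        "metrics_symptomatic": m_sym,
        "sensitivity_ci": (se_low, se_high),
        "alert_rate": n_alert / n_quest,
        "detecting_questionnaire_share_all": (
            agg["detecting_questionnaires"] / agg["irae_associated_questionnaires"]
        ),
        "detecting_questionnaire_share_symptomatic": (
            agg["detecting_questionnaires"]
            / agg["irae_associated_questionnaires_symptomatic"]
        ),
        "green_followed_by_irae_rate": (
            agg["green_followed_by_irae"] / agg["score_counts"]["green"]
        ),
        "false_alert_cause_proportions": {
            k: v / n_false for k, v in causes.items()
        },
        "label_total_check": (
            agg["score_counts"]["green"]
            + agg["score_counts"]["orange"]
            + agg["score_counts"]["red"]
            + agg["prior_irae_alert_questionnaires"]
        ),
    }
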