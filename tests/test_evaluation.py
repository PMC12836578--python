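import datetime as dt
import math
import random

import pytest

from eprotriage.evaluation import (
    ConfusionCounts,
    FalseAlertCause,
    InconsistentCohortError,
    MissReason,
    QLabel,
    QuestionnaireLabel,
    cause_summary,
    confusion_counts,
    default_relatedness,
    diagnostic_metrics,
    link_detections,
    time_saved,
    wilson_ci,
)
from eprotriage.model import ITEM_IDS, IrAEEvent, VisitSchedule
from eprotriage.triage import score_questionnaire

from conftest import make_questionnaire


def scored(q):
    return (q, score_questionnaire(q))


def day(offset, hour=10):
    return dt.datetime(2021, 3, 1, hour) + dt.timedelta(days=offset)


def make_irae(irae_id="e1", pid="p1", category="skin_toxicity", grade=2,
              diagnosed=dt.date(2021, 3, 10), symptomatic=True, related=frozenset()):
    return IrAEEvent(
        irae_id=irae_id, patient_id=pid, category=category, ctcae_grade=grade,
        diagnosed_at=diagnosed, symptomatic=symptomatic, related_items=related,
    )


class TestWilsonCI:
    def test_frozen_value_for_27_of_69(self):
        low, high = wilson_ci(27, 69, 0.95)
        assert low == pytest.approx(0.2848, abs=5e-5)
        assert high == pytest.approx(0.5093, abs=5e-5)

    def test_matches_closed_form(self):
        # independent closed-form evaluation of the score interval
        z = 1.959963984540054
        for k, n in [(3, 17), (27, 69), (50, 50)]:
            p = k / n
            centre = (p + z * z / (2 * n)) / (1 + z * z / n)
            half = (z / (1 + z * z / n)) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
            low, high = wilson_ci(k, n)
            assert low == pytest.approx(centre - half, abs=1e-12)
            assert high == pytest.approx(centre + half, abs=1e-12)

    def test_boundaries_are_exact(self):
        assert wilson_ci(0, 10)[0] == 0.0
        assert wilson_ci(10, 10)[1] == 1.0

    def test_wider_level_widens_interval(self):
        low95, high95 = wilson_ci(27, 69, 0.95)
        low99, high99 = wilson_ci(27, 69, 0.99)
        assert low99 < low95 < 27 / 69 < high95 < high99

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestConfusionCounts:
    def test_reference_tallies_give_published_tn(self):
        cc = ConfusionCounts(27, 42, 761, 4394, prior_quest=25)
        assert cc.tn_quest == 4352

    def test_negative_tn_is_inconsistent_cohort(self):
        with pytest.raises(InconsistentCohortError):
            ConfusionCounts(0, 5, 0, 3)

    def test_empty_cohort_all_zero(self):
        cc = confusion_counts([], [])
        assert (cc.tp_irae, cc.fn_irae, cc.fp_quest, cc.green_quest) == (0, 0, 0, 0)


class TestDiagnosticMetrics:
    def test_published_headline_metrics(self):
        cc = ConfusionCounts(27, 42, 761, 4394)
        m = diagnostic_metrics(cc)
        assert m["sensitivity"].point == pytest.approx(0.391, abs=5e-4)
        assert m["specificity"].point == pytest.approx(0.851, abs=5e-4)
        assert m["ppv"].point == pytest.approx(0.034, abs=5e-4)
        assert m["npv"].point == pytest.approx(0.990, abs=5e-4)
        for est in m.values():
            assert est.ci_low <= est.point <= est.ci_high
            assert 0.0 <= est.ci_low and est.ci_high <= 1.0

    def test_perfect_detection(self):
        m = diagnostic_metrics(ConfusionCounts(1, 0, 0, 10))
        assert m["sensitivity"].point == 1.0
        assert m["npv"].point == 1.0

    def test_zero_denominator_flagged_undefined(self):
        m = diagnostic_metrics(ConfusionCounts(0, 0, 0, 0))
        assert not m["sensitivity"].defined
        assert m["sensitivity"].point is None


class TestLinkDetections:
    def test_related_alert_before_diagnosis_detects_with_lead(self):
        qs = [scored(make_questionnaire("q1", completed_at=day(6), rash=2))]
        irae = make_irae(diagnosed=dt.date(2021, 3, 10))
        links, labels = link_detections(qs, [irae])
        (ln,) = links
        assert ln.detecting_questionnaire == "q1"
        assert ln.lead_days == 3
        assert labels[0].label is QLabel.ALERT_DETECTING

    def test_unrelated_alert_does_not_detect(self):
        qs = [scored(make_questionnaire("q1", completed_at=day(6), headache=2))]
        irae = make_irae(category="colitis_digestive", diagnosed=dt.date(2021, 3, 10))
        links, labels = link_detections(qs, [irae])
        assert not links[0].detected
        assert links[0].miss_reason is MissReason.SYMPTOMS_NOT_REPORTED
        assert labels[0].label is QLabel.ALERT_FALSE

    def test_only_first_of_successive_alerts_detects(self):
        qs = [
            scored(make_questionnaire("q1", completed_at=day(4), rash=2)),
            scored(make_questionnaire("q2", completed_at=day(7), rash=2)),
        ]
        irae = make_irae(diagnosed=dt.date(2021, 3, 10))
        links, labels = link_detections(qs, [irae])
        assert links[0].detecting_questionnaire == "q1"
        by_ref = {lb.questionnaire_ref: lb.label for lb in labels}
        assert by_ref["q1"] is QLabel.ALERT_DETECTING
        assert by_ref["q2"] is QLabel.ALERT_PRIOR_IRAE

    def test_same_day_tie_broken_by_questionnaire_id(self):
        qs = [
            scored(make_questionnaire("q2", completed_at=day(6, hour=8), rash=2)),
            scored(make_questionnaire("q1", completed_at=day(6, hour=20), rash=2)),
        ]
        links, _ = link_detections(qs, [make_irae(diagnosed=dt.date(2021, 3, 10))])
        assert links[0].detecting_questionnaire == "q1"

    def test_one_questionnaire_may_detect_simultaneous_events(self):
        qs = [scored(make_questionnaire("q1", completed_at=day(6), rash=2, diarrhea=2))]
        iraes = [
            make_irae("e1", category="skin_toxicity", diagnosed=dt.date(2021, 3, 10)),
            make_irae("e2", category="colitis_digestive", diagnosed=dt.date(2021, 3, 10)),
        ]
        links, labels = link_detections(qs, iraes)
        assert all(ln.detecting_questionnaire == "q1" for ln in links)
        assert labels[0].label is QLabel.ALERT_DETECTING

    def test_alert_outside_window_does_not_detect(self):
        qs = [scored(make_questionnaire("q1", completed_at=day(0), rash=2))]
        irae = make_irae(diagnosed=dt.date(2021, 5, 1))
        links, _ = link_detections(qs, [irae], window_days=30)
        assert not links[0].detected

    def test_miss_reason_priority_order(self):
        # blood-only beats everything, even with no questionnaire at all
        blood = make_irae("e1", symptomatic=False, category="thyroiditis")
        # symptomatic but no completed questionnaire in the window
        far = make_irae("e2", diagnosed=dt.date(2021, 8, 1))
        # symptomatic, questionnaire present, but category has no items
        uninstr = make_irae("e3", category="mixed_connective_tissue",
                            diagnosed=dt.date(2021, 3, 10))
        # symptomatic, questionnaire present, items exist, not reported
        silent = make_irae("e4", diagnosed=dt.date(2021, 3, 10))
        qs = [scored(make_questionnaire("q1", completed_at=day(6)))]  # green
        links, _ = link_detections(qs, [blood, far, uninstr, silent])
        reasons = {ln.irae_ref: ln.miss_reason for ln in links}
        assert reasons["e1"] is MissReason.BLOOD_DISORDER_NO_CLINICAL_IMPACT
        assert reasons["e2"] is MissReason.QUESTIONNAIRE_NOT_COMPLETED
        assert reasons["e3"] is MissReason.SYMPTOMS_NOT_IN_QUESTIONNAIRE
        assert reasons["e4"] is MissReason.SYMPTOMS_NOT_REPORTED

    def test_blood_only_event_ignores_category_item_map(self):
        # a fatigue alert must not "detect" an asymptomatic thyroiditis
        qs = [scored(make_questionnaire("q1", completed_at=day(6), fatigue=2))]
        irae = make_irae(symptomatic=False, category="thyroiditis",
                         diagnosed=dt.date(2021, 3, 10))
        links, labels = link_detections(qs, [irae])
        assert not links[0].detected
        assert labels[0].label is QLabel.ALERT_FALSE

    def test_explicit_related_items_override_category_map(self):
        qs = [scored(make_questionnaire("q1", completed_at=day(6), fever=2))]
        irae = make_irae(category="skin_toxicity", related=frozenset({"fever"}),
                         diagnosed=dt.date(2021, 3, 10))
        links, _ = link_detections(qs, [irae])
        assert links[0].detected

    def test_related_alert_after_diagnosis_is_prior_not_false(self):
        qs = [scored(make_questionnaire("q1", completed_at=day(15), rash=2))]
        irae = make_irae(diagnosed=dt.date(2021, 3, 10))
        links, labels = link_detections(qs, [irae])
        assert not links[0].detected
        assert labels[0].label is QLabel.ALERT_PRIOR_IRAE

    def test_detection_implies_lead_within_window(self):
        rng = random.Random(7)
        for _ in range(20):
            links, _ = _random_cohort_links(rng, window=14)
            for ln in links:
                if ln.detected:
                    assert 0 <= ln.lead_days <= 14

    def test_agrees_with_brute_force_on_random_small_cohorts(self):
        rng = random.Random(20210301)
        relmap = default_relatedness()
        for _ in range(60):
            qs, iraes, window = _random_cohort(rng)
            links, _ = link_detections(qs, iraes, window_days=window)
            expected = {
                e.irae_id: _brute_force_detector(e, qs, window, relmap) for e in iraes
            }
            got = {ln.irae_ref: ln.detecting_questionnaire for ln in links}
            assert got == expected


def _random_cohort(rng):
    """Small random cohort: <=20 questionnaires, <=5 events, 1-3 patients."""
    window = rng.choice([7, 14, 30])
    pids = [f"p{i}" for i in range(rng.randint(1, 3))]
    qs = []
    for i in range(rng.randint(0, 20)):
        grades = {}
        for item in rng.sample(ITEM_IDS, rng.randint(0, 3)):
            grades[item] = rng.randint(0, 3)
        q = make_questionnaire(
            f"q{i:02d}", rng.choice(pids),
            completed_at=day(rng.randint(0, 60), hour=rng.randint(8, 20)),
            **grades,
        )
        qs.append(scored(q))
    cats = ["skin_toxicity", "colitis_digestive", "thyroiditis", "rheumatological",
            "hyperlipasemia", "mixed_connective_tissue"]
    iraes = [
        make_irae(
            f"e{j}", rng.choice(pids), category=rng.choice(cats),
            grade=rng.randint(2, 4),
            diagnosed=dt.date(2021, 3, 1) + dt.timedelta(days=rng.randint(0, 60)),
            symptomatic=rng.random() > 0.3,
        )
        for j in range(rng.randint(0, 5))
    ]
    return qs, iraes, window


def _brute_force_detector(irae, scored_qs, window, relmap):
    """Exhaustive search over all (questionnaire, event) pairs."""
    if irae.related_items:
        related = set(irae.related_items)
    elif not irae.symptomatic:
        related = set()
    else:
        related = set(relmap.get(irae.category, ()))
    candidates = []
    for q, s in scored_qs:
        if q.patient_id != irae.patient_id or s.color.value == "green":
            continue
        lead = (irae.diagnosed_at - q.completed_at.date()).days
        flagged = {r.item_id for r in q.responses if r.grade >= 2}
        if 0 <= lead <= window and flagged & related:
            candidates.append((q.completed_at.date(), q.questionnaire_id))
    return min(candidates)[1] if candidates else None


def _random_cohort_links(rng, window):
    qs, iraes, _ = _random_cohort(rng)
    return link_detections(qs, iraes, window_days=window)


class TestTimeSaved:
    sched = VisitSchedule("p1", (dt.date(2021, 3, 10), dt.date(2021, 4, 21)))

    def _detected_link(self, detected_at):
        qs = [scored(make_questionnaire("q1",
                                        completed_at=dt.datetime.combine(detected_at, dt.time(10)),
                                        rash=2))]
        return qs

    def test_diagnosis_on_visit_day_saves_nothing(self):
        irae = make_irae(diagnosed=dt.date(2021, 3, 10))
        links, _ = link_detections(self._detected_link(dt.date(2021, 3, 8)), [irae])
        assert time_saved(links[0], self.sched, irae.diagnosed_at) == 0

    def test_early_detection_saves_days_to_next_visit(self):
        irae = make_irae(diagnosed=dt.date(2021, 4, 1))
        links, _ = link_detections(self._detected_link(dt.date(2021, 3, 29)), [irae])
        # next visit after 29 Mar is 21 Apr; 20 days before it
        assert time_saved(links[0], self.sched, irae.diagnosed_at) == 20

    def test_hand_arithmetic_case(self):
        sched = VisitSchedule("p1", (dt.date(2021, 3, 15),))  # 7 days after detection
        irae = make_irae(diagnosed=dt.date(2021, 3, 11))  # 3 days after detection
        links, _ = link_detections(self._detected_link(dt.date(2021, 3, 8)), [irae])
        assert time_saved(links[0], sched, irae.diagnosed_at) == 4

    def test_no_future_visit_is_undefined(self):
        sched = VisitSchedule("p1", (dt.date(2021, 3, 1),))
        irae = make_irae(diagnosed=dt.date(2021, 3, 10))
        links, _ = link_detections(self._detected_link(dt.date(2021, 3, 8)), [irae])
        assert time_saved(links[0], sched, irae.diagnosed_at) is None

    def test_undetected_event_rejected(self):
        irae = make_irae(diagnosed=dt.date(2021, 3, 10))
        links, _ = link_detections([], [irae])
        with pytest.raises(ValueError):
            time_saved(links[0], self.sched, irae.diagnosed_at)


class TestCauseSummary:
    def test_published_cause_proportions(self):
        counts = {
            "functional_nonspecific": 246, "previous_condition": 142,
            "independent_condition": 140, "input_error": 111,
            "overestimated_grade1": 63, "tumor_burden": 59,
        }
        labels, causes = [], {}
        i = 0
        for cause, n in counts.items():
            for _ in range(n):
                ref = f"q{i}"
                labels.append(QuestionnaireLabel(ref, QLabel.ALERT_FALSE))
                causes[ref] = FalseAlertCause(cause)
                i += 1
        out = cause_summary(labels, causes)
        expected = {
            "functional_nonspecific": 0.323, "previous_condition": 0.187,
            "independent_condition": 0.184, "input_error": 0.146,
            "overestimated_grade1": 0.083, "tumor_burden": 0.078,
        }
        for cause, prop in expected.items():
            assert out[cause]["proportion"] == pytest.approx(prop, abs=5e-4)
        assert sum(v["count"] for v in out.values()) == 761

    def test_no_false_alerts_gives_empty_summary(self):
        labels = [QuestionnaireLabel("q1", QLabel.ALERT_DETECTING)]
        assert cause_summary(labels, {}) == {}

    def test_single_false_alert(self):
        labels = [QuestionnaireLabel("q1", QLabel.ALERT_FALSE)]
        out = cause_summary(labels, {"q1": FalseAlertCause.INPUT_ERROR})
        assert out["input_error"] == {"count": 1, "proportion": 1.0}

    def test_missing_annotation_named(self):
        labels = [QuestionnaireLabel("q9", QLabel.ALERT_FALSE)]
        with pytest.raises(KeyError, match="q9"):
            cause_summary(labels, {})


class TestSymptomaticSubset:
    def test_dropping_blood_only_misses_raises_sensitivity(self):
        qs = [scored(make_questionnaire("q1", completed_at=day(6), rash=2))]
        iraes = [
            make_irae("e1", diagnosed=dt.date(2021, 3, 10)),  # detected
            make_irae("e2", symptomatic=False, category="thyroiditis",
                      diagnosed=dt.date(2021, 3, 20)),
            make_irae("e3", symptomatic=False, category="hyperlipasemia",
                      diagnosed=dt.date(2021, 3, 25)),
        ]
        # need greens to keep tn_quest >= 0
        qs += [scored(make_questionnaire(f"g{i}", completed_at=day(20 + i)))
               for i in range(5)]
        links, labels = link_detections(qs, iraes)
        cc_all = confusion_counts(links, labels)
        cc_sym = confusion_counts(links, labels, symptomatic_only=True)
        assert (cc_all.tp_irae, cc_all.fn_irae) == (1, 2)
        assert (cc_sym.tp_irae, cc_sym.fn_irae) == (1, 0)
        se_all = diagnostic_metrics(cc_all)["sensitivity"].point
        se_sym = diagnostic_metrics(cc_sym)["sensitivity"].point
        assert se_sym >= se_all
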