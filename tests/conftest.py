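import datetime as dt

import pytest

from eprotriage.model import ITEM_IDS, Questionnaire, SymptomResponse


def make_questionnaire(
    qid="q1",
    pid="p1",
    completed_at=dt.datetime(2021, 3, 2, 10, 0),
    **grades,
):
    """Questionnaire with every item grade 0 except the keyword
    overrides, e.g. ``make_questionnaire(fatigue=2, rash=3)``."""
    unknown = set(grades) - set(ITEM_IDS)
    if unknown:
        raise ValueError(f"unknown items {unknown}")
    responses = tuple(
        SymptomResponse(item, grades.get(item, 0)) for item in ITEM_IDS
    )
    return Questionnaire(
        questionnaire_id=qid,
        patient_id=pid,
        completed_at=completed_at,
        responses=responses,
    )


@pytest.fixture
def quest_factory():
    return make_questionnaire
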