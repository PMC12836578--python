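"""Readers and writers for the cohort table set.

The on-disk layout is a directory of plain CSV files (comma-separated,
UTF-8, mandatory header row, ISO-8601 dates): ``patients.csv``,
``questionnaires.csv`` (wide format by default, long format accepted),
``iraes.csv``, ``visits.csv`` and optionally ``ground_truth.csv`` with
simulator annotations.  A lossless JSON mirror of the whole bundle is
also provided for nested export.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .evaluation import FalseAlertCause
from .model import (
    ITEM_IDS,
    IrAEEvent,
    Patient,
    Questionnaire,
    SymptomResponse,
    VisitSchedule,
    validate_questionnaire,
)

__all__ = ["CohortBundle", "BundleFormatError", "read_bundle", "write_bundle"]


class BundleFormatError(ValueError):
    """Schema, parse or referential-integrity failure, located by file
    and row where possible."""


@dataclass
class CohortBundle:
    """In-memory cohort: patients, their questionnaires, IrAE registry,
    visit schedules, and optional simulator ground truth (per-IrAE
    detectability flags and per-questionnaire false-alert causes)."""

    patients: dict[str, Patient] = field(default_factory=dict)
    questionnaires: list[Questionnaire] = field(default_factory=list)
    iraes: list[IrAEEvent] = field(default_factory=list)
    visit_schedules: dict[str, VisitSchedule] = field(default_factory=dict)
    ground_truth: Optional[dict[str, bool]] = None
    causes: Optional[dict[str, str]] = None

    def validate(self) -> "CohortBundle":
        """Referential integrity plus per-questionnaire validation."""
        for q in self.questionnaires:
            if q.patient_id not in self.patients:
                raise BundleFormatError(
                    f"questionnaire {q.questionnaire_id!r} references unknown "
                    f"patient {q.patient_id!r}"
                )
            validate_questionnaire(q)
            p = self.patients[q.patient_id]
            if q.completed_at.date() < p.enrolled_at:
                raise BundleFormatError(
                    f"questionnaire {q.questionnaire_id!r} completed before "
                    f"enrollment of patient {q.patient_id!r}"
                )
        for e in self.iraes:
            if e.patient_id not in self.patients:
                raise BundleFormatError(
                    f"IrAE {e.irae_id!r} references unknown patient {e.patient_id!r}"
                )
        for pid in self.visit_schedules:
            if pid not in self.patients:
                raise BundleFormatError(
                    f"visit schedule references unknown patient {pid!r}"
                )
        return self


def _parse_date(value, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise BundleFormatError(f"{where}: unparseable date {value!r}") from exc


def _parse_datetime(value, where: str) -> dt.datetime:
    try:
        return dt.datetime.fromisoformat(str(value))
    except ValueError as exc:
        raise BundleFormatError(f"{where}: unparseable timestamp {value!r}") from exc


def _opt(value):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return value


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise BundleFormatError(f"{fname}: missing required columns {missing}")


def _read_patients(path: Path) -> dict[str, Patient]:
    df = _read_csv(path)
    _require_columns(
        df,
        ["patient_id", "sex", "age_years", "regimen", "indication",
         "cerebral_metastasis", "enrolled_at"],
        path.name,
    )
    patients: dict[str, Patient] = {}
    for i, row in df.iterrows():
        where = f"{path.name} row {i + 2}"
        pid = row["patient_id"]
        if pid in patients:
            raise BundleFormatError(f"{where}: duplicate patient_id {pid!r}")
        disc = _opt(row.get("discontinued_at", ""))
        patients[pid] = Patient(
            patient_id=pid,
            sex=row["sex"],
            age_years=int(row["age_years"]),
            regimen=row["regimen"],
            indication=row["indication"],
            cerebral_metastasis=row["cerebral_metastasis"] in ("1", "True", "true"),
            enrolled_at=_parse_date(row["enrolled_at"], where),
            discontinued_at=_parse_date(disc, where) if disc else None,
            discontinuation_reason=_opt(row.get("discontinuation_reason", "")),
        )
    return patients


def _questionnaire_from_wide(row, where: str) -> Questionnaire:
    responses = tuple(
        SymptomResponse(item_id, int(row[item_id])) for item_id in ITEM_IDS
    )
    return Questionnaire(
        questionnaire_id=row["questionnaire_id"],
        patient_id=row["patient_id"],
        completed_at=_parse_datetime(row["completed_at"], where),
        responses=responses,
        free_text=_opt(row.get("free_text", "")),
        callback_requested=row.get("callback_requested", "") in ("1", "True", "true"),
    )


def _read_questionnaires(path: Path) -> list[Questionnaire]:
    df = _read_csv(path)
    if "item_id" in df.columns:  # long format: one row per response
        _require_columns(
            df, ["patient_id", "questionnaire_id", "completed_at", "item_id", "grade"],
            path.name,
        )
        out = []
        for (qid,), grp in df.groupby(["questionnaire_id"], sort=False):
            where = f"{path.name} questionnaire {qid!r}"
            first = grp.iloc[0]
            responses = tuple(
                SymptomResponse(r["item_id"], int(r["grade"]))
                for _, r in grp.iterrows()
            )
            out.append(
                Questionnaire(
                    questionnaire_id=qid,
                    patient_id=first["patient_id"],
                    completed_at=_parse_datetime(first["completed_at"], where),
                    responses=responses,
                )
            )
        return out
    _require_columns(
        df, ["patient_id", "questionnaire_id", "completed_at", *ITEM_IDS], path.name
    )
    return [
        _questionnaire_from_wide(row, f"{path.name} row {i + 2}")
        for i, row in df.iterrows()
    ]


def _read_iraes(path: Path) -> list[IrAEEvent]:
    df = _read_csv(path)
    _require_columns(
        df,
        ["irae_id", "patient_id", "category", "ctcae_grade", "diagnosed_at",
         "symptomatic"],
        path.name,
    )
    events = []
    for i, row in df.iterrows():
        where = f"{path.name} row {i + 2}"
        related = frozenset(
            s for s in str(row.get("related_items", "")).split(";") if s
        )
        managed = _opt(row.get("managed_at", ""))
        events.append(
            IrAEEvent(
                irae_id=row["irae_id"],
                patient_id=row["patient_id"],
                category=row["category"],
                ctcae_grade=int(row["ctcae_grade"]),
                diagnosed_at=_parse_date(row["diagnosed_at"], where),
                symptomatic=row["symptomatic"] in ("1", "True", "true"),
                related_items=related,
                managed_at=_parse_date(managed, where) if managed else None,
            )
        )
    return events


def _read_visits(path: Path) -> dict[str, VisitSchedule]:
    df = _read_csv(path)
    _require_columns(df, ["patient_id", "visit_date"], path.name)
    by_patient: dict[str, list[dt.date]] = {}
    for i, row in df.iterrows():
        where = f"{path.name} row {i + 2}"
        by_patient.setdefault(row["patient_id"], []).append(
            _parse_date(row["visit_date"], where)
        )
    return {
        pid: VisitSchedule(pid, tuple(sorted(dates)))
        for pid, dates in by_patient.items()
    }


def _read_ground_truth(path: Path) -> tuple[dict[str, bool], dict[str, str]]:
    df = _read_csv(path)
    _require_columns(df, ["record_type", "ref_id", "value"], path.name)
    detectable: dict[str, bool] = {}
    causes: dict[str, str] = {}
    for i, row in df.iterrows():
        kind = row["record_type"]
        if kind == "irae_detectable":
            detectable[row["ref_id"]] = row["value"] in ("1", "True", "true")
        elif kind == "false_alert_cause":
            causes[row["ref_id"]] = FalseAlertCause(row["value"]).value
        else:
            raise BundleFormatError(
                f"{path.name} row {i + 2}: unknown record_type {kind!r}"
            )
    return detectable, causes


def read_bundle(directory) -> CohortBundle:
    """Load and validate a cohort bundle from a directory of CSV files."""
    d = Path(directory)
    for required in ("patients.csv", "questionnaires.csv"):
        if not (d / required).exists():
            raise BundleFormatError(f"missing required file {required} in {d}")
    bundle = CohortBundle(
        patients=_read_patients(d / "patients.csv"),
        questionnaires=_read_questionnaires(d / "questionnaires.csv"),
        iraes=_read_iraes(d / "iraes.csv") if (d / "iraes.csv").exists() else [],
        visit_schedules=(
            _read_visits(d / "visits.csv") if (d / "visits.csv").exists() else {}
        ),
    )
    if (d / "ground_truth.csv").exists():
        detectable, causes = _read_ground_truth(d / "ground_truth.csv")
        bundle.ground_truth = detectable
        bundle.causes = causes
    return bundle.validate()


_PATIENT_COLS = [
    "patient_id", "sex", "age_years", "regimen", "indication",
    "cerebral_metastasis", "enrolled_at", "discontinued_at",
    "discontinuation_reason",
]


def _patients_frame(bundle: CohortBundle) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "age_years": p.age_years,
                "regimen": p.regimen,
                "indication": p.indication,
                "cerebral_metastasis": int(p.cerebral_metastasis),
                "enrolled_at": p.enrolled_at.isoformat(),
                "discontinued_at": (
                    p.discontinued_at.isoformat() if p.discontinued_at else ""
                ),
                "discontinuation_reason": p.discontinuation_reason or "",
            }
            for p in bundle.patients.values()
        ],
        columns=_PATIENT_COLS,
    )


def _questionnaires_frame(bundle: CohortBundle, long: bool = False) -> pd.DataFrame:
    if long:
        rows = [
            {
                "patient_id": q.patient_id,
                "questionnaire_id": q.questionnaire_id,
                "completed_at": q.completed_at.isoformat(),
                "item_id": r.item_id,
                "grade": r.grade,
            }
            for q in bundle.questionnaires
            for r in q.responses
        ]
        return pd.DataFrame(
            rows,
            columns=["patient_id", "questionnaire_id", "completed_at",
                     "item_id", "grade"],
        )
    rows = []
    for q in bundle.questionnaires:
        row = {
            "patient_id": q.patient_id,
            "questionnaire_id": q.questionnaire_id,
            "completed_at": q.completed_at.isoformat(),
        }
        row.update({r.item_id: r.grade for r in q.responses})
        row["free_text"] = q.free_text or ""
        row["callback_requested"] = int(q.callback_requested)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["patient_id", "questionnaire_id", "completed_at", *ITEM_IDS,
                 "free_text", "callback_requested"],
    )


def _iraes_frame(bundle: CohortBundle) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "irae_id": e.irae_id,
                "patient_id": e.patient_id,
                "category": e.category,
                "ctcae_grade": e.ctcae_grade,
                "diagnosed_at": e.diagnosed_at.isoformat(),
                "symptomatic": int(e.symptomatic),
                "related_items": ";".join(sorted(e.related_items)),
                "managed_at": e.managed_at.isoformat() if e.managed_at else "",
            }
            for e in bundle.iraes
        ],
        columns=["irae_id", "patient_id", "category", "ctcae_grade",
                 "diagnosed_at", "symptomatic", "related_items", "managed_at"],
    )


def write_bundle(bundle: CohortBundle, directory, long_questionnaires: bool = False) -> None:
    """Write the bundle as the standard CSV file set (plus ground truth
    when present).  Deterministic: equal bundles give byte-identical
    files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _patients_frame(bundle).to_csv(d / "patients.csv", index=False)
    _questionnaires_frame(bundle, long=long_questionnaires).to_csv(
        d / "questionnaires.csv", index=False
    )
    _iraes_frame(bundle).to_csv(d / "iraes.csv", index=False)
    visit_rows = [
        {"patient_id": pid, "visit_date": day.isoformat()}
        for pid, sched in bundle.visit_schedules.items()
        for day in sched.visit_dates
    ]
    pd.DataFrame(visit_rows, columns=["patient_id", "visit_date"]).to_csv(
        d / "visits.csv", index=False
    )
    if bundle.ground_truth is not None or bundle.causes is not None:
        gt_rows = [
            {"record_type": "irae_detectable", "ref_id": ref, "value": int(flag)}
            for ref, flag in sorted((bundle.ground_truth or {}).items())
        ] + [
            {"record_type": "false_alert_cause", "ref_id": ref, "value": cause}
            for ref, cause in sorted((bundle.causes or {}).items())
        ]
        pd.DataFrame(gt_rows, columns=["record_type", "ref_id", "value"]).to_csv(
            d / "ground_truth.csv", index=False
        )


def bundle_to_json(bundle: CohortBundle) -> str:
    """Lossless nested JSON mirror of the bundle."""
    obj = {
        "patients": json.loads(_patients_frame(bundle).to_json(orient="records")),
        "questionnaires": json.loads(
            _questionnaires_frame(bundle).to_json(orient="records")
        ),
        "iraes": json.loads(_iraes_frame(bundle).to_json(orient="records")),
        "visits": {
            pid: [d.isoformat() for d in s.visit_dates]
            for pid, s in bundle.visit_schedules.items()
        },
        "ground_truth": bundle.ground_truth,
        "causes": bundle.causes,
    }
    return json.dumps(obj, indent=2, sort_keys=True)
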