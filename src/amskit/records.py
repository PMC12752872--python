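"""Patient-record schema for subcutaneous immunotherapy (SCIT) follow-up.

A record set is a list of :class:`PatientRecord`: demographics, diagnoses
(allergic rhinitis AR, asthma AS, atopic dermatitis AD), medication
courses, allergen injections, follow-up visits with questionnaire scores,
and lung-function measurements.

Parsing and validation are deliberately separate: :func:`load_records`
only enforces types and enum membership (a malformed date is a parse
error), while cross-field clinical invariants — birth date before
enrolment, non-decreasing cumulative injection dose, lesion area only for
AD patients — are checked by :func:`validate_records`, which reports
problems instead of raising. This lets imperfect real-world exports be
loaded, inspected, and triaged.

File formats: a JSON record-set file ``{"schema_version": 1,
"patients": [...]}``, and a CSV form with one row per patient where the
nested lists are JSON-encoded cells (both round-trip exactly). A separate
flat CSV export, one row per injection, serves spreadsheet consumers.
"""

from __future__ import annotations

import json
from datetime import date
from enum import Enum
from pathlib import Path
from typing import List, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import RecordParseError
from .units import Dose, unit_family

SCHEMA_VERSION = 1

#: Questionnaire instruments the platform records at follow-up visits.
QUESTIONNAIRES = ("VAS", "ACT", "ACQ", "RQLQ", "AQLQ", "EASI", "SCORAD")


class Sex(str, Enum):
    male = "male"
    female = "female"


class Diagnosis(str, Enum):
    AR = "AR"  # allergic rhinitis
    AS = "AS"  # asthma
    AD = "AD"  # atopic dermatitis


class DoseModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    value: float = Field(ge=0)
    unit: str = "application"

    def as_dose(self) -> Dose:
        return Dose(self.value, self.unit)


class MedicationCourse(BaseModel):
    """One drug's usage episode: dose per administration, administrations
    per day, and days of use starting at ``start_date``."""

    model_config = ConfigDict(extra="forbid")

    drug_id: str
    dose_per_administration: DoseModel
    frequency_per_day: float = Field(gt=0)
    period_days: float = Field(ge=0)
    start_date: date


class InjectionRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    date: date
    vial_number: int = Field(ge=1)
    cumulative_dose: float  # allergen units; sign checked by validate_records
    injection_site: str = ""
    adverse_reaction: Optional[str] = None


class FollowUpVisit(BaseModel):
    model_config = ConfigDict(extra="forbid")

    date: date
    questionnaire_scores: dict = Field(default_factory=dict)
    lesion_area_percent: Optional[float] = None


class LungFunctionRecord(BaseModel):
    """Spirometry values; PEF in L/min, FEV1/FVC in L, ratio a fraction."""

    model_config = ConfigDict(extra="forbid")

    date: date
    pef: Optional[float] = None
    fev1: Optional[float] = None
    fvc: Optional[float] = None
    fev1_fvc_ratio: Optional[float] = None


class PatientRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patient_id: str
    sex: Sex
    birth_date: date
    enrolment_date: date
    diagnoses: List[Diagnosis]
    courses: List[MedicationCourse] = Field(default_factory=list)
    injections: List[InjectionRecord] = Field(default_factory=list)
    visits: List[FollowUpVisit] = Field(default_factory=list)
    lung_function: List[LungFunctionRecord] = Field(default_factory=list)

    def age_at(self, reference: Optional[date] = None) -> int:
        """Completed years at ``reference`` (default: enrolment date)."""
        ref = reference or self.enrolment_date
        years = ref.year - self.birth_date.year
        if (ref.month, ref.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        return years


class Severity(str, Enum):
    error = "error"
    warning = "warning"


class Issue(BaseModel):
    locator: str
    severity: Severity
    message: str


class ValidationReport(BaseModel):
    issues: List[Issue] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == Severity.error for i in self.issues)

    def errors(self) -> List[Issue]:
        return [i for i in self.issues if i.severity == Severity.error]


# --------------------------------------------------------------------- I/O

_CSV_COLUMNS = [
    "patient_id", "sex", "birth_date", "enrolment_date", "diagnoses",
    "courses", "injections", "visits", "lung_function",
]


def _record_to_jsonable(rec: PatientRecord) -> dict:
    return json.loads(rec.model_dump_json())


def _normalize(rec: PatientRecord) -> PatientRecord:
    rec.visits.sort(key=lambda v: v.date)
    rec.injections.sort(key=lambda i: (i.date, i.vial_number))
    return rec


def _parse_patient(obj: dict, where: str) -> PatientRecord:
    try:
        return _normalize(PatientRecord.model_validate(obj))
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise RecordParseError(
            f"{where}: field {loc!r}: {first['msg']}"
        ) from exc


def load_records(path, format: str = "json") -> List[PatientRecord]:
    """Read a record set; visits come back sorted ascending by date.

    ``format`` is ``"json"`` (record-set file) or ``"csv"`` (one row per
    patient, nested lists JSON-encoded). Unknown enum values or malformed
    dates raise :class:`RecordParseError` naming the record and field.
    """
    path = Path(path)
    if format == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise RecordParseError(f"{path}: invalid JSON: {exc}") from exc
        patients = payload.get("patients", []) if isinstance(payload, dict) else payload
        return [
            _parse_patient(obj, f"{path}: patients[{i}]")
            for i, obj in enumerate(patients)
        ]
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        out = []
        for i, row in enumerate(df.to_dict("records")):
            obj = {
                "patient_id": row["patient_id"],
                "sex": row["sex"],
                "birth_date": row["birth_date"],
                "enrolment_date": row["enrolment_date"],
                "diagnoses": row["diagnoses"].split(";") if row["diagnoses"] else [],
            }
            for col in ("courses", "injections", "visits", "lung_function"):
                try:
                    obj[col] = json.loads(row[col]) if row.get(col) else []
                except json.JSONDecodeError as exc:
                    raise RecordParseError(
                        f"{path}: row {i}: field {col!r}: invalid JSON"
                    ) from exc
            out.append(_parse_patient(obj, f"{path}: row {i}"))
        return out
    raise ValueError(f"unknown format {format!r}")


def write_records(records, path, format: str = "json") -> None:
    """Serialize a record set; inverse of :func:`load_records`."""
    path = Path(path)
    if format == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "patients": [_record_to_jsonable(r) for r in records],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    if format == "csv":
        rows = []
        for rec in records:
            obj = _record_to_jsonable(rec)
            rows.append({
                "patient_id": obj["patient_id"],
                "sex": obj["sex"],
                "birth_date": obj["birth_date"],
                "enrolment_date": obj["enrolment_date"],
                "diagnoses": ";".join(obj["diagnoses"]),
                "courses": json.dumps(obj["courses"]),
                "injections": json.dumps(obj["injections"]),
                "visits": json.dumps(obj["visits"]),
                "lung_function": json.dumps(obj["lung_function"]),
            })
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
        return
    raise ValueError(f"unknown format {format!r}")


# -------------------------------------------------------------- validation

def validate_records(records) -> ValidationReport:
    """Check every cross-field invariant; problems become report entries,
    never exceptions. Idempotent and side-effect free."""
    issues: List[Issue] = []

    def err(locator: str, message: str) -> None:
        issues.append(Issue(locator=locator, severity=Severity.error,
                            message=message))

    def warn(locator: str, message: str) -> None:
        issues.append(Issue(locator=locator, severity=Severity.warning,
                            message=message))

    seen: dict = {}
    for idx, rec in enumerate(records):
        loc = f"patients[{idx}] ({rec.patient_id})"
        if not rec.patient_id:
            err(loc, "empty patient_id")
        elif rec.patient_id in seen:
            err(loc, f"duplicate patient_id also at patients[{seen[rec.patient_id]}]")
        else:
            seen[rec.patient_id] = idx

        if not rec.diagnoses:
            err(loc, "diagnoses must be non-empty")
        if len(set(rec.diagnoses)) != len(rec.diagnoses):
            warn(loc, "repeated diagnosis codes")
        if rec.birth_date > rec.enrolment_date:
            err(loc, f"birth_date {rec.birth_date} after enrolment_date "
                     f"{rec.enrolment_date}")

        dates = [v.date for v in rec.visits]
        if dates != sorted(dates):
            err(loc, "visits not sorted ascending by date")

        has_ad = Diagnosis.AD in rec.diagnoses
        for j, v in enumerate(rec.visits):
            for name in v.questionnaire_scores:
                if name not in QUESTIONNAIRES:
                    err(f"{loc}.visits[{j}]", f"unknown questionnaire {name!r}")
            if v.lesion_area_percent is not None:
                if not 0 <= v.lesion_area_percent <= 100:
                    err(f"{loc}.visits[{j}]",
                        f"lesion_area_percent {v.lesion_area_percent} "
                        "outside [0, 100]")
                if not has_ad:
                    err(f"{loc}.visits[{j}]",
                        "lesion_area_percent recorded without AD diagnosis")

        last_cum: dict = {}
        for j, inj in enumerate(rec.injections):
            if inj.cumulative_dose < 0:
                err(f"{loc}.injections[{j}]",
                    f"negative cumulative_dose {inj.cumulative_dose}")
            prev = last_cum.get(inj.vial_number)
            if prev is not None and inj.cumulative_dose < prev:
                err(f"{loc}.injections[{j}]",
                    f"cumulative_dose decreases within vial {inj.vial_number}")
            last_cum[inj.vial_number] = inj.cumulative_dose

        for j, lf in enumerate(rec.lung_function):
            for name in ("pef", "fev1", "fvc", "fev1_fvc_ratio"):
                val = getattr(lf, name)
                if val is not None and val <= 0:
                    err(f"{loc}.lung_function[{j}]", f"{name} must be > 0")
            if lf.fev1 is not None and lf.fvc is not None and lf.fev1 > lf.fvc:
                err(f"{loc}.lung_function[{j}]",
                    f"fev1 {lf.fev1} exceeds fvc {lf.fvc}")

        for j, c in enumerate(rec.courses):
            try:
                unit_family(c.dose_per_administration.unit)
            except Exception:
                err(f"{loc}.courses[{j}]",
                    f"unknown dose unit {c.dose_per_administration.unit!r}")

    return ValidationReport(issues=issues)


# ------------------------------------------------------------- flat export

#: Fixed column order of the flat (one row per injection) export.
FLAT_COLUMNS = [
    "patient_id", "sex", "birth_date", "enrolment_date", "diagnoses",
    "injection_date", "vial_number", "cumulative_dose", "injection_site",
    "adverse_reaction",
]


def export_flat(records) -> pd.DataFrame:
    """Flatten a record set to one row per injection, demographics repeated.

    Row count equals the total injection count across patients.
    """
    rows = []
    for rec in records:
        diag = ";".join(d.value for d in rec.diagnoses)
        for inj in rec.injections:
            rows.append({
                "patient_id": rec.patient_id,
                "sex": rec.sex.value,
                "birth_date": rec.birth_date.isoformat(),
                "enrolment_date": rec.enrolment_date.isoformat(),
                "diagnoses": diag,
                "injection_date": inj.date.isoformat(),
                "vial_number": inj.vial_number,
                "cumulative_dose": inj.cumulative_dose,
                "injection_site": inj.injection_site,
                "adverse_reaction": inj.adverse_reaction or "",
            })
    return pd.DataFrame(rows, columns=FLAT_COLUMNS)
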