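"""Cohort-level summaries and follow-up schedule logic.

Summaries mirror the registry-style demographic table: sex counts with
one-decimal percentages (half-up rounding, so rounded cells need not sum
to exactly 100), age bands 3–5 / 6–17 / 18–40 / 41–64 / ≥65 years, median
age with interquartile range, the seven diagnosis-combination classes
(AR, AS, AR+AS, AS+AD, AR+AD, AR+AS+AD, other), and enrolment-year
counts. Also here: nonattendance ("shedding") detection from the gap
since the last injection, and next-appointment arithmetic from a
phase→interval schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional

import numpy as np

from .errors import DomainError, SchedulingError
from .records import Diagnosis, PatientRecord

AGE_BANDS = ("3-5", "6-17", "18-40", "41-64", ">=65")
DISEASE_CLASSES = ("AR", "AS", "AR+AS", "AS+AD", "AR+AD", "AR+AS+AD", "other")

#: Default injection intervals per treatment phase, in days. Escalation is
#: conventionally weekly and maintenance four-weekly; clinics override.
DEFAULT_SCHEDULE = {"escalation": 7, "maintenance": 28}


def percentage(count: int, total: int) -> float:
    """100·count/total rounded half-up to one decimal (table convention)."""
    if total <= 0:
        raise DomainError("total must be positive")
    if count < 0 or count > total:
        raise DomainError(f"count {count} outside [0, {total}]")
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def median_iqr(values) -> tuple:
    """(median, q1, q3) by linear interpolation on the order statistics."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise DomainError("median_iqr of an empty list")
    med, q1, q3 = np.percentile(vals, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


def age_band(age_years: int) -> str:
    """Band label for a completed age; ages below 3 fall into the first
    band so the partition is exhaustive."""
    if age_years < 6:
        return "3-5"
    if age_years < 18:
        return "6-17"
    if age_years < 41:
        return "18-40"
    if age_years < 65:
        return "41-64"
    return ">=65"


def disease_class(diagnoses) -> str:
    """Map a diagnosis set to one of the seven combination classes."""
    s = {Diagnosis(d) for d in diagnoses}
    table = {
        frozenset({Diagnosis.AR}): "AR",
        frozenset({Diagnosis.AS}): "AS",
        frozenset({Diagnosis.AR, Diagnosis.AS}): "AR+AS",
        frozenset({Diagnosis.AS, Diagnosis.AD}): "AS+AD",
        frozenset({Diagnosis.AR, Diagnosis.AD}): "AR+AD",
        frozenset({Diagnosis.AR, Diagnosis.AS, Diagnosis.AD}): "AR+AS+AD",
    }
    return table.get(frozenset(s), "other")


@dataclass
class CohortSummary:
    n_total: int
    sex_counts: Dict[str, int]
    sex_percents: Dict[str, float]
    age_band_counts: Dict[str, int]
    age_median: Optional[float]
    age_iqr: Optional[tuple]
    disease_counts: Dict[str, int]
    disease_percents: Dict[str, float]
    year_counts: Dict[int, int]


def summarize(records, reference_date: Optional[date] = None) -> CohortSummary:
    """Build the demographic summary; ages at ``reference_date`` (default:
    each patient's enrolment date). Every count partition sums to n_total."""
    n = len(records)
    sex_counts = {"male": 0, "female": 0}
    band_counts = {b: 0 for b in AGE_BANDS}
    dis_counts = {c: 0 for c in DISEASE_CLASSES}
    year_counts: Dict[int, int] = {}
    ages: List[int] = []
    for rec in records:
        sex_counts[rec.sex.value] += 1
        age = rec.age_at(reference_date)
        ages.append(age)
        band_counts[age_band(age)] += 1
        dis_counts[disease_class(rec.diagnoses)] += 1
        year_counts[rec.enrolment_date.year] = (
            year_counts.get(rec.enrolment_date.year, 0) + 1
        )
    if n:
        med, q1, q3 = median_iqr(ages)
        sex_pct = {k: percentage(v, n) for k, v in sex_counts.items()}
        dis_pct = {k: percentage(v, n) for k, v in dis_counts.items()}
    else:
        med, q1, q3 = None, None, None
        sex_pct = {k: 0.0 for k in sex_counts}
        dis_pct = {k: 0.0 for k in dis_counts}
    return CohortSummary(
        n_total=n,
        sex_counts=sex_counts,
        sex_percents=sex_pct,
        age_band_counts=band_counts,
        age_median=med,
        age_iqr=None if med is None else (q1, q3),
        disease_counts=dis_counts,
        disease_percents=dis_pct,
        year_counts=dict(sorted(year_counts.items())),
    )


@dataclass
class AdherenceEntry:
    patient_id: str
    last_injection_date: Optional[date]
    expected_next_date: Optional[date]
    days_overdue: int
    flagged: bool
    reason: Optional[str] = None


@dataclass
class AdherenceReport:
    entries: List[AdherenceEntry] = field(default_factory=list)

    def flagged(self) -> List[AdherenceEntry]:
        return [e for e in self.entries if e.flagged]


def detect_nonattendance(
    record: PatientRecord,
    expected_interval_days: int,
    grace_days: int,
    as_of: date,
) -> AdherenceEntry:
    """Flag a patient as non-attending when the gap since the last
    injection strictly exceeds interval + grace."""
    if expected_interval_days <= 0:
        raise DomainError("expected_interval_days must be positive")
    if grace_days < 0:
        raise DomainError("grace_days must be non-negative")
    if not record.injections:
        return AdherenceEntry(
            patient_id=record.patient_id,
            last_injection_date=None,
            expected_next_date=None,
            days_overdue=0,
            flagged=False,
            reason="no injections",
        )
    last = max(i.date for i in record.injections)
    expected_next = last + timedelta(days=expected_interval_days)
    overdue = (as_of - last).days - (expected_interval_days + grace_days)
    flagged = overdue > 0
    return AdherenceEntry(
        patient_id=record.patient_id,
        last_injection_date=last,
        expected_next_date=expected_next,
        days_overdue=max(overdue, 0),
        flagged=flagged,
        reason="overdue" if flagged else None,
    )


def adherence_report(
    records, expected_interval_days: int, grace_days: int, as_of: date
) -> AdherenceReport:
    return AdherenceReport(entries=[
        detect_nonattendance(r, expected_interval_days, grace_days, as_of)
        for r in records
    ])


def current_phase(record: PatientRecord, escalation_injections: int = 15) -> str:
    """Treatment phase from the injection count: dose escalation until the
    configured number of injections, maintenance after."""
    return (
        "escalation"
        if len(record.injections) < escalation_injections
        else "maintenance"
    )


def next_appointment(
    record: PatientRecord,
    schedule: Optional[Dict[str, int]] = None,
    escalation_injections: int = 15,
) -> date:
    """Last injection date plus the configured interval for the patient's
    current phase."""
    if not record.injections:
        raise SchedulingError(
            f"patient {record.patient_id}: no injections to schedule from"
        )
    sched = dict(DEFAULT_SCHEDULE)
    if schedule:
        sched.update(schedule)
    phase = current_phase(record, escalation_injections)
    if phase not in sched:
        raise SchedulingError(f"no interval configured for phase {phase!r}")
    last = max(i.date for i in record.injections)
    return last + timedelta(days=int(sched[phase]))
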