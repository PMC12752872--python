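"""Average Medication Score (AMS) computation.

The AMS summarizes a patient's drug burden over a follow-up window as

    AMS = Σ_drugs (total dose / unit dose) × frequency × period × unit score
                  ───────────────────────────────────────────────────────────
                                     follow-up days

where *total dose* is the dose per administration, *frequency* is
administrations per day, *period* is days of use inside the window,
*unit dose*/*unit score* come from the formulary policy, and *follow-up
days* is the window length. One unit-dose taken daily through the whole
window therefore contributes exactly frequency × unit score, independent
of window length; more drugs, higher doses, or longer use raise the
score, and a lower AMS indicates better disease control.

For atopic dermatitis the score of dermatitis-category drugs carries an
extra lesion-area coefficient: the affected body-surface percentage
measured in patient palms (one palm ≈ 1%), with 1% as the neutral
standard. A 3% lesion area triples those drugs' contribution.

Windows are half-open ``[start, end)`` so consecutive follow-up windows
never double-count a treatment day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import List, Optional

from .errors import DomainError
from .formulary import Formulary, points_per_administration
from .records import MedicationCourse, PatientRecord


@dataclass(frozen=True)
class ScoringWindow:
    """A follow-up interval ``[start, end)``; its day count is the AMS
    denominator."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DomainError(
                f"window end {self.end} must be after start {self.start}"
            )

    @property
    def follow_up_days(self) -> int:
        return (self.end - self.start).days

    def overlap_days(self, course_start: date, period_days: float) -> float:
        """Days of ``[course_start, course_start + period)`` inside the
        window (fractional periods allowed)."""
        if period_days <= 0:
            return 0.0
        lo = max(course_start, self.start)
        hi_f = (course_start - self.start).days + period_days
        hi = min(hi_f, float(self.follow_up_days))
        lo_f = float((lo - self.start).days)
        return max(0.0, hi - lo_f)


@dataclass(frozen=True)
class DermatitisContext:
    """Lesion-area coefficient for dermatitis scoring, in percent of body
    surface area (one patient palm ≈ 1%)."""

    lesion_area_percent: float

    def __post_init__(self) -> None:
        if not 0 <= self.lesion_area_percent <= 100:
            raise DomainError(
                f"lesion area {self.lesion_area_percent}% outside [0, 100]"
            )


@dataclass
class AMSResult:
    window: ScoringWindow
    per_course: List[tuple] = field(default_factory=list)  # (drug_id, points)
    total: float = 0.0


def lesion_area_from_palms(palm_count: float) -> float:
    """Convert a palm count to a body-surface percentage (1 palm = 1%),
    capped at 100."""
    if palm_count < 0:
        raise DomainError(f"palm count must be non-negative, got {palm_count}")
    return min(palm_count * 1.0, 100.0)


def course_ams(
    course: MedicationCourse,
    window: ScoringWindow,
    formulary: Formulary,
) -> float:
    """AMS contribution of one medication course over one window.

    The course's period is clipped to its overlap with the window, so a
    course outside the window scores 0 and splitting a course into
    contiguous sub-courses leaves the score unchanged.
    """
    effective_period = window.overlap_days(course.start_date, course.period_days)
    if effective_period == 0.0:
        return 0.0
    entry = formulary.get(course.drug_id)
    per_admin = points_per_administration(
        entry, course.dose_per_administration.as_dose(), formulary
    )
    return (
        per_admin * course.frequency_per_day * effective_period
        / window.follow_up_days
    )


def dermatitis_ams(base_points: float, context: DermatitisContext) -> float:
    """Apply the lesion-area coefficient: percent number as multiplier,
    1% is the identity."""
    if base_points < 0:
        raise DomainError("base points must be non-negative")
    return base_points * context.lesion_area_percent


def _window_lesion_area(record: PatientRecord, window: ScoringWindow):
    """Latest recorded lesion area at a visit inside the window, or None."""
    area = None
    for v in record.visits:
        if window.start <= v.date < window.end and v.lesion_area_percent is not None:
            area = v.lesion_area_percent
    return area


def patient_ams(
    record: PatientRecord,
    window: ScoringWindow,
    formulary: Formulary,
    lesion_area_percent: Optional[float] = None,
) -> AMSResult:
    """Total AMS of a patient over one window: the sum over courses.

    Dermatitis-category drugs are multiplied by the lesion-area
    coefficient when an area is recorded at a visit inside the window (the
    latest such visit wins) or passed explicitly; with no recorded area
    the coefficient is 1.
    """
    area = lesion_area_percent
    if area is None:
        area = _window_lesion_area(record, window)

    per_course: List[tuple] = []
    total = 0.0
    for course in record.courses:
        pts = course_ams(course, window, formulary)
        if area is not None:
            entry = formulary.get(course.drug_id)
            if entry.disease_category == "dermatitis":
                pts = dermatitis_ams(pts, DermatitisContext(area))
        if pts > 0:
            per_course.append((course.drug_id, pts))
        total += pts
    return AMSResult(window=window, per_course=per_course, total=total)


def ams_timeline(record: PatientRecord, formulary: Formulary) -> List[AMSResult]:
    """AMS series over consecutive visit pairs: one result per window
    ``[visit_i, visit_{i+1})``. Fewer than two visits yields an empty list.

    The series is reported as-is; interpreting a falling AMS as improving
    control is left to the caller.
    """
    visits = sorted(record.visits, key=lambda v: v.date)
    results = []
    for a, b in zip(visits, visits[1:]):
        if b.date <= a.date:
            continue  # same-day visits define no window
        window = ScoringWindow(a.date, b.date)
        results.append(patient_ams(record, window, formulary))
    return results
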