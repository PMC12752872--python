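"""AMS arithmetic: hand-derived window scores, the dermatitis lesion-area
coefficient, timeline fenceposting, and a day-by-day accumulation oracle."""

from datetime import date, timedelta

import numpy as np
import pytest

from amskit import (
    DermatitisContext,
    ScoringWindow,
    ams_timeline,
    course_ams,
    dermatitis_ams,
    lesion_area_from_palms,
    patient_ams,
)
from amskit.errors import DomainError
from amskit.records import (
    Diagnosis,
    DoseModel,
    FollowUpVisit,
    MedicationCourse,
    PatientRecord,
    Sex,
)

from conftest import make_course

WINDOW_30D = ScoringWindow(date(2023, 1, 1), date(2023, 1, 31))


def make_patient(courses, visits=(), diagnoses=(Diagnosis.AR,)):
    return PatientRecord(
        patient_id="T1",
        sex=Sex.male,
        birth_date=date(2000, 1, 1),
        enrolment_date=date(2022, 1, 1),
        diagnoses=list(diagnoses),
        courses=list(courses),
        visits=list(visits),
    )


class TestScoringWindow:
    def test_follow_up_days(self):
        assert WINDOW_30D.follow_up_days == 30

    def test_degenerate_window_rejected(self):
        with pytest.raises(DomainError):
            ScoringWindow(date(2023, 1, 1), date(2023, 1, 1))

    def test_overlap_clips_to_window(self):
        # course starts 10 days before the window, runs 15 days into it
        assert WINDOW_30D.overlap_days(date(2022, 12, 22), 25) == 15.0
        assert WINDOW_30D.overlap_days(date(2023, 1, 20), 90) == 11.0
        assert WINDOW_30D.overlap_days(date(2023, 3, 1), 30) == 0.0


class TestCourseAms:
    def test_once_daily_unit_dose_over_full_window(self, formulary):
        # 10 mg loratadine (unit score 2 at 10 mg), once daily, 30 days
        course = make_course("loratadine_tab", 10, "mg", freq=1, period=30)
        assert course_ams(course, WINDOW_30D, formulary) == pytest.approx(2.0)

    def test_nebulized_twice_daily(self, formulary):
        # 1 mg budesonide suspension (10 points), twice daily, 30/30 days
        course = make_course("budesonide_suspension", 1, "mg", freq=2,
                             period=30)
        assert course_ams(course, WINDOW_30D, formulary) == pytest.approx(20.0)

    def test_zero_period_scores_zero(self, formulary):
        course = make_course("loratadine_tab", 10, "mg", period=0)
        assert course_ams(course, WINDOW_30D, formulary) == 0.0

    def test_course_outside_window_scores_zero(self, formulary):
        course = make_course("loratadine_tab", 10, "mg",
                             start=date(2024, 1, 1))
        assert course_ams(course, WINDOW_30D, formulary) == 0.0

    def test_combination_course(self, formulary):
        # Symbicort 160/4.5 (2 pts/inhalation), 2 inhalations/day, full window
        course = make_course("symbicort_160_4_5", 1, "application", freq=2,
                             period=30)
        assert course_ams(course, WINDOW_30D, formulary) == pytest.approx(4.0)

    def test_persistent_daily_use_is_window_length_invariant(self, formulary):
        for days in (7, 28, 30, 90):
            window = ScoringWindow(date(2023, 1, 1),
                                   date(2023, 1, 1) + timedelta(days=days))
            course = make_course("loratadine_tab", 10, "mg", freq=1,
                                 period=days)
            assert course_ams(course, window, formulary) == pytest.approx(2.0)

    def test_monotone_in_each_factor(self, formulary):
        base = make_course("loratadine_tab", 10, "mg", freq=1, period=10)
        ref = course_ams(base, WINDOW_30D, formulary)
        higher_dose = make_course("loratadine_tab", 20, "mg", freq=1,
                                  period=10)
        more_frequent = make_course("loratadine_tab", 10, "mg", freq=2,
                                    period=10)
        longer = make_course("loratadine_tab", 10, "mg", freq=1, period=20)
        assert course_ams(higher_dose, WINDOW_30D, formulary) > ref
        assert course_ams(more_frequent, WINDOW_30D, formulary) > ref
        assert course_ams(longer, WINDOW_30D, formulary) > ref
        shorter_followup = ScoringWindow(date(2023, 1, 1), date(2023, 1, 16))
        assert course_ams(base, shorter_followup, formulary) > ref

    def test_splitting_a_course_preserves_the_score(self, formulary):
        whole = make_course("budesonide_inhaled", 160, "ug", freq=2, period=20)
        first = make_course("budesonide_inhaled", 160, "ug", freq=2, period=8)
        second = make_course("budesonide_inhaled", 160, "ug", freq=2,
                             period=12, start=date(2023, 1, 9))
        assert course_ams(whole, WINDOW_30D, formulary) == pytest.approx(
            course_ams(first, WINDOW_30D, formulary)
            + course_ams(second, WINDOW_30D, formulary)
        )


ORACLE_DRUGS = [
    # (drug_id, ref_dose_ug or None for count units, ref_score)
    ("budesonide_inhaled", 80.0, 0.5),
    ("fluticasone_inhaled", 125.0, 1.0),
    ("loratadine_tab", 10_000.0, 2.0),
    ("budesonide_suspension", 1_000.0, 10.0),
    ("prednisone_tab", 5_000.0, 20.0),
    ("saline_irrigation", None, 0.1),
]


class TestDayByDayOracle:
    def test_matches_on_1000_random_cases(self, formulary):
        """course_ams must equal a literal walk over calendar days: on each
        window day the course is active, add (dose/ref dose) × ref score ×
        frequency; finally divide by window length."""
        rng = np.random.default_rng(20240917)
        for _ in range(1000):
            drug_id, ref_ug, ref_score = ORACLE_DRUGS[
                rng.integers(0, len(ORACLE_DRUGS))
            ]
            if ref_ug is None:
                dose_value, unit, dose_ug = 1.0, "application", None
            else:
                dose_value = float(rng.uniform(0.1, 3.0)) * ref_ug
                unit, dose_ug = "ug", dose_value
            freq = float(rng.integers(1, 4))
            period = int(rng.integers(0, 60))
            win_len = int(rng.integers(1, 60))
            win_start = date(2023, 1, 1) + timedelta(
                days=int(rng.integers(0, 90)))
            window = ScoringWindow(win_start,
                                   win_start + timedelta(days=win_len))
            course_start = win_start + timedelta(
                days=int(rng.integers(-30, 60)))
            course = make_course(drug_id, dose_value, unit, freq=freq,
                                 period=period, start=course_start)

            per_admin = ref_score * (1.0 if dose_ug is None
                                     else dose_ug / ref_ug)
            expected = 0.0
            day = win_start
            course_end = course_start + timedelta(days=period)
            while day < window.end:
                if course_start <= day < course_end:
                    expected += per_admin * freq
                day += timedelta(days=1)
            expected /= win_len

            got = course_ams(course, window, formulary)
            assert got == pytest.approx(expected, abs=1e-9)
            assert got >= 0.0


class TestDermatitisCoefficient:
    def test_one_percent_is_the_identity(self):
        assert dermatitis_ams(0.5, DermatitisContext(1.0)) == 0.5

    def test_three_percent_triples(self):
        assert dermatitis_ams(0.5, DermatitisContext(3.0)) == pytest.approx(1.5)

    def test_zero_area_zeroes_the_score(self):
        assert dermatitis_ams(7.7, DermatitisContext(0.0)) == 0.0

    def test_out_of_range_area_rejected(self):
        with pytest.raises(DomainError):
            DermatitisContext(101.0)
        with pytest.raises(DomainError):
            DermatitisContext(-1.0)

    def test_palm_rule(self):
        assert lesion_area_from_palms(1) == 1.0
        assert lesion_area_from_palms(0) == 0.0
        assert lesion_area_from_palms(150) == 100.0
        with pytest.raises(DomainError):
            lesion_area_from_palms(-1)


class TestPatientAms:
    def test_no_courses_gives_zero_total(self, formulary):
        result = patient_ams(make_patient([]), WINDOW_30D, formulary)
        assert result.total == 0.0
        assert result.per_course == []

    def test_singleton_sum(self, formulary):
        course = make_course("loratadine_tab", 10, "mg", period=30)
        result = patient_ams(make_patient([course]), WINDOW_30D, formulary)
        assert result.total == pytest.approx(
            course_ams(course, WINDOW_30D, formulary))

    def test_two_course_total(self, formulary):
        courses = [
            make_course("loratadine_tab", 10, "mg", freq=1, period=30),
            make_course("budesonide_suspension", 1, "mg", freq=2, period=30),
        ]
        result = patient_ams(make_patient(courses), WINDOW_30D, formulary)
        assert result.total == pytest.approx(22.0)
        assert result.total == pytest.approx(
            sum(p for _, p in result.per_course))

    def test_lesion_area_multiplies_dermatitis_drugs_only(self, formulary):
        courses = [
            make_course("mometasone_cream", 1, "application", freq=1,
                        period=30),
            make_course("loratadine_tab", 10, "mg", freq=1, period=30),
        ]
        visit = FollowUpVisit(date=date(2023, 1, 10), lesion_area_percent=3.0)
        rec = make_patient(courses, visits=[visit],
                           diagnoses=(Diagnosis.AR, Diagnosis.AD))
        result = patient_ams(rec, WINDOW_30D, formulary)
        scores = dict(result.per_course)
        assert scores["mometasone_cream"] == pytest.approx(0.5 * 3)
        assert scores["loratadine_tab"] == pytest.approx(2.0)

    def test_missing_lesion_area_means_coefficient_one(self, formulary):
        course = make_course("mometasone_cream", 1, "application", period=30)
        rec = make_patient([course], diagnoses=(Diagnosis.AD,))
        result = patient_ams(rec, WINDOW_30D, formulary)
        assert result.total == pytest.approx(0.5)


class TestTimeline:
    def visits(self, *dates_):
        return [FollowUpVisit(date=d) for d in dates_]

    def test_three_visits_two_windows(self, formulary):
        rec = make_patient([], visits=self.visits(
            date(2023, 1, 1), date(2023, 2, 1), date(2023, 3, 1)))
        assert len(ams_timeline(rec, formulary)) == 2

    def test_fewer_than_two_visits_empty(self, formulary):
        rec = make_patient([], visits=self.visits(date(2023, 1, 1)))
        assert ams_timeline(rec, formulary) == []

    def test_constant_daily_course_equal_in_every_window(self, formulary):
        course = make_course("loratadine_tab", 10, "mg", freq=1, period=120,
                             start=date(2023, 1, 1))
        rec = make_patient([course], visits=self.visits(
            date(2023, 1, 1), date(2023, 1, 29), date(2023, 3, 1),
            date(2023, 4, 15)))
        totals = [r.total for r in ams_timeline(rec, formulary)]
        assert len(totals) == 3
        assert all(t == pytest.approx(2.0) for t in totals)

    def test_course_confined_to_first_window(self, formulary):
        course = make_course("loratadine_tab", 10, "mg", period=10,
                             start=date(2023, 1, 2))
        rec = make_patient([course], visits=self.visits(
            date(2023, 1, 1), date(2023, 2, 1), date(2023, 3, 1)))
        first, second = ams_timeline(rec, formulary)
        assert first.total > 0
        assert second.total == 0.0
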