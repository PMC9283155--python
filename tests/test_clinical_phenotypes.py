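"""HOMA indices, unit conversions, OGTT/postpartum classification, diet scores."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prs_gxe import (
    DietActivityRecord,
    OgttRecord,
    ValidationError,
    VisitRecord,
    classify_early_and_booking,
    classify_postpartum,
    derive_cohort_phenotypes,
    diagnose_gdm,
    hba1c_pct_to_mmol_mol,
    hfii_score,
    homa_b,
    homa_ir,
    success_score,
)


class TestHomaIndices:
    @pytest.mark.parametrize(
        "glucose,insulin,expected",
        [
            (22.5, 6.0, 1.0),       # 6 pmol/l = 1 µU/ml; normalizing constant
            (5.0, 60.0, 5 * 10 / 22.5),
            (5.0, 0.0, 0.0),
        ],
    )
    def test_homa_ir(self, glucose, insulin, expected):
        assert homa_ir(glucose, insulin) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "glucose,insulin,expected",
        [
            (5.5, 60.0, 100.0),   # 20 x 10 / 2.0
            (4.5, 6.0, 20.0),     # 20 x 1 / 1.0
        ],
    )
    def test_homa_b(self, glucose, insulin, expected):
        assert homa_b(glucose, insulin) == pytest.approx(expected)

    def test_homa_b_singularity(self):
        with pytest.raises(ValidationError):
            homa_b(3.5, 60.0)

    def test_missing_propagates_not_zero(self):
        assert math.isnan(homa_ir(math.nan, 60.0))
        assert math.isnan(homa_b(5.5, math.nan))


class TestHba1cConversion:
    @pytest.mark.parametrize("pct,expected", [(5.25, 34), (5.39, 35), (2.16, 0)])
    def test_examples(self, pct, expected):
        assert hba1c_pct_to_mmol_mol(pct) == expected

    def test_below_intercept_is_domain_error(self):
        with pytest.raises(ValidationError):
            hba1c_pct_to_mmol_mol(2.15)


class TestDiagnoseGdm:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((5.3, 9.0, 7.0), True),     # fasting boundary is inclusive
            ((5.2, 9.9, 8.5), False),    # all strictly below
            ((4.8, 10.5, 8.0), True),    # 1 h criterion
            ((4.8, None, 8.6), True),    # 2-point test, 2 h boundary
            ((5.0, None, 7.0), False),
        ],
    )
    def test_thresholds(self, triple, expected):
        assert diagnose_gdm(OgttRecord(*triple)) is expected

    def test_unmeasured_is_missing_not_negative(self):
        assert diagnose_gdm(OgttRecord()) is None
        assert diagnose_gdm(None) is None

    @given(
        g0=st.floats(3.0, 12.0),
        g1=st.floats(3.0, 16.0),
        g2=st.floats(3.0, 14.0),
        bump=st.floats(0.0, 5.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_glucose(self, g0, g1, g2, bump):
        base = diagnose_gdm(OgttRecord(g0, g1, g2))
        raised = diagnose_gdm(OgttRecord(g0 + bump, g1, g2))
        if base:
            assert raised


class TestEarlyAndBooking:
    def _visits(self, positive):
        triple = (5.5, 9.0, 7.0) if positive else (4.8, 8.0, 7.0)
        return [VisitRecord("T1", ogtt=OgttRecord(*triple))]

    def test_early_recruit_positive_enrolment_is_booking(self):
        early, booking = classify_early_and_booking(self._visits(True), "early_pregnancy")
        assert early and booking

    def test_prepregnancy_recruit_cannot_have_booking(self):
        early, booking = classify_early_and_booking(self._visits(True), "pre_pregnancy")
        assert early and not booking

    def test_all_negative(self):
        early, booking = classify_early_and_booking(self._visits(False), "early_pregnancy")
        assert early is False and booking is False

    def test_missing_first_trimester_ogtt_gives_missing_flags(self):
        assert classify_early_and_booking([], "pre_pregnancy") == (None, None)


class TestClassifyPostpartum:
    @pytest.mark.parametrize(
        "fg,g2,expected_label",
        [
            (6.5, 7.0, "IFG"),
            (7.0, 6.0, "T2D"),
            (5.0, 7.7, "normal"),
            (6.2, 8.0, "IFG+IGT"),
            (5.5, 11.1, "T2D"),
            (5.5, 10.9, "IGT"),
            (6.9, None, "IFG"),  # upper IFG bound inclusive
        ],
    )
    def test_bands(self, fg, g2, expected_label):
        visit = VisitRecord(
            "pp12mo",
            fasting_glucose=fg,
            ogtt=OgttRecord(glucose_2h=g2) if g2 is not None else None,
        )
        diag = classify_postpartum(visit)
        assert diag.label == expected_label
        assert diag.abnormal == (expected_label != "normal")

    def test_physician_diagnosis_forces_abnormal(self):
        visit = VisitRecord("pp12mo", physician_diagnosed_diabetes=True)
        assert classify_postpartum(visit).abnormal

    def test_nothing_measured_is_missing(self):
        assert classify_postpartum(VisitRecord("pp12mo")) is None

    @given(fg=st.floats(4.0, 9.0), bump=st.floats(0.0, 3.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_fasting_glucose(self, fg, bump):
        a = classify_postpartum(VisitRecord("pp12mo", fasting_glucose=fg))
        b = classify_postpartum(VisitRecord("pp12mo", fasting_glucose=fg + bump))
        if a.abnormal:
            assert b.abnormal


class TestDietScores:
    def _record(self, points):
        names = [
            "snacks", "sugar_sweetened_beverages", "fast_food",
            "high_fibre_grains", "fat_spread", "low_fat_cheese",
            "low_fat_milk", "fish", "red_processed_meat", "vegetables",
            "fruits_berries",
        ]
        return DietActivityRecord(**dict(zip(names, points)))

    def test_maximum_is_18(self):
        assert hfii_score(self._record([2, 1, 1, 2, 2, 1, 2, 2, 2, 2, 1])) == 18

    def test_all_zero(self):
        assert hfii_score(self._record([0] * 11)) == 0

    def test_hand_sum(self):
        assert hfii_score(self._record([2, 1, 1, 2, 2, 1, 2, 0, 0, 1, 0])) == 12

    def test_component_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            hfii_score(self._record([3, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]))

    @pytest.mark.parametrize(
        "kwargs,expected_points,expected_success",
        [
            (dict(fibre_g_per_day=35, fruit_veg_portions_per_day=6,
                  saturated_fat_pct_energy=8, gwg_category="adequate",
                  pa_min_per_week=200), 5, True),
            (dict(fibre_g_per_day=30, fruit_veg_portions_per_day=5,
                  saturated_fat_pct_energy=12, gwg_category="above",
                  pa_min_per_week=150), 3, True),
            (dict(fibre_g_per_day=20, fruit_veg_portions_per_day=5,
                  saturated_fat_pct_energy=12, gwg_category="below",
                  pa_min_per_week=30), 2, False),
        ],
    )
    def test_success_score(self, kwargs, expected_points, expected_success):
        points, success = success_score(DietActivityRecord(**kwargs))
        assert (points, success) == (expected_points, expected_success)

    def test_missing_goal_contributes_zero(self):
        points, success = success_score(
            DietActivityRecord(fibre_g_per_day=35, pa_min_per_week=180)
        )
        assert (points, success) == (2, False)


class TestCohortDerivation:
    def test_simulated_labels_round_trip(self, small_study):
        """The classifiers recover every label the generator planted."""
        derived = derive_cohort_phenotypes(small_study.cohort)
        for derived_col, true_col in [
            ("gdm", "true_gdm"),
            ("early_gdm", "true_early_gdm"),
            ("booking_gdm", "true_booking_gdm"),
            ("pp12_abnormal", "true_pp12_abnormal"),
        ]:
            np.testing.assert_array_equal(
                derived[derived_col].to_numpy(), derived[true_col].to_numpy()
            )

    def test_homa_and_hba1c_columns_added(self, small_study):
        derived = derive_cohort_phenotypes(small_study.cohort)
        for col in ("homa_ir_t1", "homa_b_t1", "hba1c_mmol_t1", "hfii", "success_score"):
            assert col in derived.columns
        assert derived["hfii"].between(0, 18).all()
        assert derived["success_score"].between(0, 5).all()
        # HOMA-B must decline with genetic risk by construction
        r = np.corrcoef(derived["homa_b_t2"], derived["prs_true_z"])[0, 1]
        assert r < 0
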