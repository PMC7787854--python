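"""ACF, ABCD, DiaRem and IMS scoring: points, bands, ranges, exclusions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2drem import scores
from t2drem.scores import (
    ACF_ATTAINABLE_TOTALS,
    MissingScoreInputError,
    PatientBaseline,
    abcd_score,
    acf_band,
    acf_score,
    diarem_score,
    ims_score,
    score_cohort,
)


def patient(**kw):
    defaults = dict(
        age=50.0, sex="male", bmi=30.0, duration=5.0, fpg=8.0, hba1c=8.0,
        fcp=2.5, cpeptide_auc=25.0, n_diabetes_medications=1,
        insulin_use=False, other_antidiabetic_drug_use=True,
    )
    defaults.update(kw)
    return PatientBaseline(**defaults)


class TestAcf:
    @pytest.mark.parametrize(
        "age, cpauc, fpg, expected",
        [
            (35, 40.0, 6.0, 9),  # all favourable
            (50, 20.0, 8.0, 0),  # all unfavourable
            (50, 40.0, 8.0, 3),  # only the C-peptide AUC component
            (40, 30.93, 7.0, 0),  # every boundary lands in the 0-point class
            (39.9, 30.94, 6.9, 9),
        ],
    )
    def test_points(self, age, cpauc, fpg, expected):
        res = acf_score(patient(age=age, cpeptide_auc=cpauc, fpg=fpg))
        assert res.points == expected
        assert res.points == sum(res.components.values())

    def test_attainable_totals_by_enumeration(self):
        reached = set()
        for age in (35, 50):
            for cpauc in (40.0, 20.0):
                for fpg in (6.0, 8.0):
                    reached.add(acf_score(patient(age=age, cpeptide_auc=cpauc,
                                                  fpg=fpg)).points)
        assert reached == set(ACF_ATTAINABLE_TOTALS)
        assert max(reached) == 9
        assert {1, 8}.isdisjoint(reached)

    def test_banding(self):
        assert acf_band(0) == "0"
        assert acf_band(2) == "2-5"
        assert acf_band(5) == "2-5"
        assert acf_band(6) == "6-9"
        assert acf_band(9) == "6-9"
        with pytest.raises(ValueError):
            acf_band(1)  # unattainable totals have no band
        with pytest.raises(ValueError):
            acf_band(8)

    def test_missing_input_not_imputed(self):
        with pytest.raises(MissingScoreInputError):
            acf_score(patient(cpeptide_auc=np.nan))

    @given(
        age=st.floats(18, 70), cpauc=st.floats(0, 200), fpg=st.floats(3, 20)
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_each_favourable_direction(self, age, cpauc, fpg):
        base = acf_score(patient(age=age, cpeptide_auc=cpauc, fpg=fpg)).points
        assert acf_score(patient(age=30, cpeptide_auc=cpauc, fpg=fpg)).points >= (
            base if age < 40 else base
        )
        assert (
            acf_score(patient(age=age, cpeptide_auc=cpauc + 50, fpg=fpg)).points
            >= base
        )
        assert (
            acf_score(patient(age=age, cpeptide_auc=cpauc, fpg=3.0)).points >= base
        )


class TestAbcd:
    def test_age_component_boundary(self):
        assert abcd_score(patient(age=39)).components["age"] == 1
        assert abcd_score(patient(age=40)).components["age"] == 0

    def test_floor_and_ceiling(self):
        lo = abcd_score(patient(age=50, bmi=25, fcp=1.0, duration=10))
        assert lo.points == 0 and lo.band == "0-2"
        hi = abcd_score(patient(age=30, bmi=45, fcp=6.0, duration=0.5))
        assert hi.points == 10 and hi.band == "9-10"

    def test_range_by_bin_enumeration(self):
        ages = (30, 50)
        bmis = (25, 30, 38, 45)
        fcps = (1.0, 2.5, 4.0, 6.0)
        durations = (0.5, 2, 6, 10)
        totals = {
            abcd_score(patient(age=a, bmi=b, fcp=c, duration=d)).points
            for a, b, c, d in itertools.product(ages, bmis, fcps, durations)
        }
        assert totals == set(range(11))


class TestDiarem:
    def test_floor_and_ceiling(self):
        lo = diarem_score(
            patient(age=30, hba1c=6.0, insulin_use=False,
                    other_antidiabetic_drug_use=False)
        )
        assert lo.points == 0 and lo.band == "0-2"
        hi = diarem_score(
            patient(age=65, hba1c=10.0, insulin_use=True,
                    other_antidiabetic_drug_use=True)
        )
        assert hi.points == 22 and hi.band == "18-22"

    def test_insulin_contributes_exactly_ten(self):
        for age, hba1c in ((30, 6.0), (55, 8.0), (65, 10.0)):
            off = diarem_score(patient(age=age, hba1c=hba1c, insulin_use=False))
            on = diarem_score(patient(age=age, hba1c=hba1c, insulin_use=True))
            assert on.points - off.points == 10

    def test_range_by_bin_enumeration(self):
        totals = {
            diarem_score(
                patient(age=a, hba1c=h, insulin_use=i,
                        other_antidiabetic_drug_use=d)
            ).points
            for a in (30, 45, 55, 65)
            for h in (6.0, 6.7, 8.0, 10.0)
            for i in (False, True)
            for d in (False, True)
        }
        assert min(totals) == 0 and max(totals) == 22
        assert totals <= set(range(23))


class TestIms:
    def test_severity_bands(self):
        mild = ims_score(
            patient(n_diabetes_medications=0, insulin_use=False, duration=0.5,
                    hba1c=6.0)
        )
        assert mild.points <= 25 and mild.band == "mild"
        moderate = ims_score(
            patient(n_diabetes_medications=1, insulin_use=False, duration=2,
                    hba1c=7.5)
        )
        assert 25 < moderate.points < 95 and moderate.band == "moderate"
        severe = ims_score(
            patient(n_diabetes_medications=3, insulin_use=True, duration=10,
                    hba1c=9.5)
        )
        assert severe.points >= 95 and severe.band == "severe"

    def test_points_monotone_in_severity(self):
        a = ims_score(patient(n_diabetes_medications=0, insulin_use=False,
                              duration=1.5, hba1c=6.5)).points
        b = ims_score(patient(n_diabetes_medications=2, insulin_use=False,
                              duration=1.5, hba1c=6.5)).points
        c = ims_score(patient(n_diabetes_medications=2, insulin_use=True,
                              duration=9.0, hba1c=9.5)).points
        assert a < b < c


class TestConservationAndCohort:
    @given(
        age=st.floats(18, 70), bmi=st.floats(20, 60), fcp=st.floats(0, 10),
        duration=st.floats(0, 15), hba1c=st.floats(4.5, 14),
        cpauc=st.floats(0, 200), fpg=st.floats(3, 20),
        nmeds=st.integers(0, 4), insulin=st.booleans(), drugs=st.booleans(),
    )
    @settings(max_examples=100, derandomize=True)
    def test_points_equal_component_sum(
        self, age, bmi, fcp, duration, hba1c, cpauc, fpg, nmeds, insulin, drugs
    ):
        p = patient(
            age=age, bmi=bmi, fcp=fcp, duration=duration, hba1c=hba1c,
            cpeptide_auc=cpauc, fpg=fpg, n_diabetes_medications=nmeds,
            insulin_use=insulin, other_antidiabetic_drug_use=drugs,
        )
        for scorer in (acf_score, abcd_score, diarem_score, ims_score):
            res = scorer(p)
            assert res.points == pytest.approx(sum(res.components.values()))

    def test_empty_cohort(self):
        out = score_cohort(pd.DataFrame(columns=["patient_id", "age"]))
        assert out.empty

    def test_listwise_exclusion_per_system(self):
        df = pd.DataFrame(
            [
                dict(patient_id="A", age=50, bmi=30, duration=5, fpg=8,
                     hba1c=8, fcp=2.5, cpeptide_auc=np.nan,
                     n_diabetes_medications=1, insulin_use=False,
                     other_antidiabetic_drug_use=True),
                dict(patient_id="B", age=35, bmi=33, duration=2, fpg=6,
                     hba1c=7, fcp=3.5, cpeptide_auc=45.0,
                     n_diabetes_medications=2, insulin_use=True,
                     other_antidiabetic_drug_use=True),
            ]
        )
        out = score_cohort(df)
        by_system = out.groupby("system")["patient_id"].apply(set)
        assert by_system["ACF"] == {"B"}  # A lacks the C-peptide AUC
        for system in ("ABCD", "DiaRem", "IMS"):
            assert by_system[system] == {"A", "B"}

    def test_full_cohort_complete(self, small_cohort):
        from t2drem import islet

        merged = small_cohort.baseline.merge(
            islet.add_indices(small_cohort.ogtt), on="patient_id"
        )
        out = score_cohort(merged)
        n = len(merged)
        counts = out.groupby("system").size()
        n_missing = int(merged["cpeptide_auc"].isna().sum())
        assert counts["ACF"] == n - n_missing
        assert counts["ABCD"] == counts["DiaRem"] == counts["IMS"] == n
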