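"""AKI/AKD/CKD classification rules and the baseline-method sensitivity."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akicohort import equations as eq
from akicohort import kdigo
from akicohort.records import (FEMALE, MALE, CreatinineSeries, DomainError,
                               ParticipantRecord, PersonParams, UrineFindings,
                               mgdl_to_umol, umol_to_mgdl)


def person(age=40.0, sex=MALE):
    return PersonParams(age=age, sex=sex)


def record(cr0, cr48=None, cr3m=None, haem=False, prot=False, age=40.0, sex=MALE):
    return ParticipantRecord(pid="x", age=age, sex=sex, cr0=cr0, cr48=cr48,
                             cr3m=cr3m, haematuria=haem, proteinuria=prot)


class TestStaging:
    @pytest.mark.parametrize("measured,baseline,expected", [
        (1.49, 1.0, 0),
        (1.5, 1.0, 1),   # boundary joins the higher stage
        (1.99, 1.0, 1),
        (2.0, 1.0, 2),
        (2.99, 1.0, 2),
        (3.0, 1.0, 3),
        (9.0, 1.0, 3),
    ])
    def test_half_open_stage_boundaries(self, measured, baseline, expected):
        assert kdigo.stage_aki(measured, baseline) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            kdigo.stage_aki(0.0, 1.0)
        with pytest.raises(DomainError):
            kdigo.stage_aki(1.0, -1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(r=st.floats(0.01, 50.0))
    def test_partition_exhaustive_and_ordered(self, r):
        s = kdigo.stage_aki(r, 1.0)
        assert s in (0, 1, 2, 3)
        assert (s >= 1) == (r >= 1.5)
        assert (s >= 2) == (r >= 2.0)
        assert (s == 3) == (r >= 3.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 20), b=st.floats(0.1, 20))
    def test_stage_monotone_in_measured(self, a, b):
        lo, hi = sorted((a, b))
        assert kdigo.stage_aki(hi, 1.0) >= kdigo.stage_aki(lo, 1.0)


class TestIncidentAKI:
    def test_baseline_aki_precludes_incident(self):
        assert kdigo.incident_aki(True, 2.0, 9.0) is False

    def test_rise_of_0p3_triggers(self):
        assert kdigo.incident_aki(False, 1.0, 1.4) is True
        assert kdigo.incident_aki(False, 1.0, 1.2) is False

    def test_missing_cr48_not_assessable(self):
        assert kdigo.incident_aki(False, 1.0, None) is None


class TestRecovery:
    def test_fall_by_48h(self):
        assert kdigo.recovery(CreatinineSeries(3.0, cr48=2.7), True) is True

    def test_normal_creatinine_at_3m(self):
        assert kdigo.recovery(CreatinineSeries(3.0, cr48=3.0, cr3m=1.2), True) is True

    def test_neither_criterion(self):
        assert kdigo.recovery(CreatinineSeries(3.0, cr48=2.9, cr3m=2.0), True) is False

    def test_not_assessable_when_both_missing(self):
        assert kdigo.recovery(CreatinineSeries(3.0), True) is None

    def test_undefined_without_aki(self):
        with pytest.raises(DomainError):
            kdigo.recovery(CreatinineSeries(3.0, cr48=2.0), False)


class TestAKD:
    def test_low_egfr(self):
        # creatinine chosen so the combined eGFR sits near 45
        scr = eq.backcalc_creatinine(45.0, person(), eq.EquationSpec(eq.MDRD4))
        assert kdigo.classify_akd(person(), scr, scr, UrineFindings()) is True

    def test_clean_normal_function(self):
        base = eq.backcalc_creatinine(90.0, person(), eq.EquationSpec(eq.MDRD4))
        assert kdigo.classify_akd(person(), base, base, UrineFindings()) is False

    def test_haematuria_alone_triggers(self):
        base = eq.backcalc_creatinine(90.0, person(), eq.EquationSpec(eq.MDRD4))
        assert kdigo.classify_akd(person(), base, base,
                                  UrineFindings(haematuria=True)) is True

    def test_creatinine_rise_over_50pct(self):
        base = eq.backcalc_creatinine(110.0, person(age=25), eq.EquationSpec(eq.MDRD4))
        assert kdigo.classify_akd(person(age=25), 1.51 * base, base, UrineFindings()) is True

    def test_any_aki_stage_implies_akd(self):
        base = eq.backcalc_creatinine(100.0, person(), eq.EquationSpec(eq.MDRD4))
        for fold in (1.5, 1.7, 2.2, 3.5):
            assert kdigo.classify_akd(person(), fold * base, base, UrineFindings()) is True


class TestCKD:
    def low_cr(self, g, age=40, sex=MALE):
        return eq.backcalc_creatinine(g, person(age, sex), eq.EquationSpec(eq.MDRD4))

    def test_low_both_timepoints(self):
        cr = self.low_cr(40.0) * 1.1  # combined eGFR safely below 60
        assert kdigo.classify_ckd(person(), CreatinineSeries(cr, cr3m=cr)) == kdigo.CKD_YES

    def test_high_presentation_is_indeterminate(self):
        cr = self.low_cr(90.0)
        assert kdigo.classify_ckd(person(), CreatinineSeries(cr, cr3m=cr)) == kdigo.CKD_INDETERMINATE

    def test_missing_cr3m_is_indeterminate(self):
        cr = self.low_cr(40.0) * 1.1
        assert kdigo.classify_ckd(person(), CreatinineSeries(cr)) == kdigo.CKD_INDETERMINATE

    def test_recovered_function_is_no(self):
        lo = self.low_cr(40.0) * 1.1
        hi = self.low_cr(95.0)
        assert kdigo.classify_ckd(person(), CreatinineSeries(lo, cr3m=hi)) == kdigo.CKD_NO


class TestBaselineEstimation:
    def test_g75_estimate_exceeds_g100(self):
        s = CreatinineSeries(1.0)
        b100 = kdigo.estimate_baseline(person(), s, kdigo.MDRD_G100).value
        b75 = kdigo.estimate_baseline(person(), s, kdigo.MDRD_G75).value
        assert b75 > b100

    def test_lowest_inpatient_is_minimum(self):
        s = CreatinineSeries(2.0, cr48=1.1)
        assert kdigo.estimate_baseline(person(), s, kdigo.LOWEST_INPATIENT).value == 1.1

    def test_mdrd_g100_matches_equation_inversion(self):
        p = person(age=38, sex=FEMALE)
        b = kdigo.estimate_baseline(p, CreatinineSeries(1.0), kdigo.MDRD_G100).value
        assert b == pytest.approx(
            eq.backcalc_creatinine(100.0, p, eq.EquationSpec(eq.MDRD4)), rel=1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(DomainError, match="unknown baseline method"):
            kdigo.estimate_baseline(person(), CreatinineSeries(1.0), "GUESS")


class TestClassifyParticipant:
    def test_threefold_rise_is_stage3_and_akd(self):
        p = person()
        base = eq.backcalc_creatinine(100.0, p, eq.EquationSpec(eq.MDRD4))
        cls = kdigo.classify_participant(record(cr0=3.0 * base))
        assert cls.aki_stage == 3
        assert cls.akd_admission is True

    def test_all_normal_record_is_negative(self):
        p = person()
        base = eq.backcalc_creatinine(100.0, p, eq.EquationSpec(eq.MDRD4))
        cls = kdigo.classify_participant(record(cr0=base, cr48=base, cr3m=base))
        assert cls.aki_stage == 0
        assert cls.incident_aki_48h is False
        assert cls.recovered is None
        assert cls.akd_admission is False
        assert cls.akd_3m is False
        assert cls.ckd == kdigo.CKD_INDETERMINATE

    def test_unit_round_trip_invariance(self):
        rec = record(cr0=2.31, cr48=1.87, cr3m=1.12)
        rt = record(cr0=umol_to_mgdl(mgdl_to_umol(2.31)),
                    cr48=umol_to_mgdl(mgdl_to_umol(1.87)),
                    cr3m=umol_to_mgdl(mgdl_to_umol(1.12)))
        a, b = kdigo.classify_participant(rec), kdigo.classify_participant(rt)
        assert a.aki_stage == b.aki_stage
        assert a.recovered == b.recovered
        assert a.akd_admission == b.akd_admission
        assert a.ckd == b.ckd

    def test_stage_monotone_in_admission_creatinine(self):
        stages = [kdigo.classify_participant(record(cr0=c)).aki_stage
                  for c in (0.9, 1.4, 1.9, 2.4, 3.1, 4.0)]
        assert stages == sorted(stages)


class TestSensitivityTable:
    def test_zero_prevalence_when_cr0_equals_baseline(self):
        recs = []
        for age in (25, 40, 60):
            p = person(age=age)
            base = eq.backcalc_creatinine(100.0, p, eq.EquationSpec(eq.MDRD4))
            recs.append(record(cr0=base, age=age))
        tab = kdigo.sensitivity_table(recs)
        assert tab.loc[kdigo.MDRD_G100, "n_aki"] == 0

    def test_empty_cohort_rejected(self):
        with pytest.raises(DomainError):
            kdigo.sensitivity_table([])

    def test_prevalence_ordering_on_cohort(self, default_cohort):
        recs, _ = default_cohort
        tab = kdigo.sensitivity_table(recs)
        assert (tab.loc[kdigo.MDRD_G75, "prevalence"]
                <= tab.loc[kdigo.MDRD_G100, "prevalence"])
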