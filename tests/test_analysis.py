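"""Statistical layer: comparisons, spline logistic + bootstrap, survival, power."""
import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from akicohort import analysis, kdigo, synth
from akicohort.records import DomainError, ParticipantRecord


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact integer hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = nums[a]
    return sum(v for v in nums.values() if v <= obs) / comb(n, c1)


class TestGroupComparisons:
    def test_fisher_matches_enumeration_oracle(self):
        for table in [(8, 27, 25, 28), (1, 9, 8, 2), (5, 5, 5, 5), (0, 10, 10, 0)]:
            a, b, c, d = table
            assert analysis.fisher_exact_p([[a, b], [c, d]]) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12)

    def test_balanced_identical_groups_give_p_one(self):
        assert analysis.fisher_exact_p([[10, 10], [10, 10]]) == pytest.approx(1.0)

    def test_constant_variable_skipped_with_note(self, default_cohort):
        recs, _ = default_cohort
        recs = [ParticipantRecord(**{**r.__dict__, "haematuria": True}) for r in recs]
        out = analysis.compare_groups(recs)
        row = out.set_index("variable").loc["haematuria"]
        assert row["test"] == "skipped"
        assert "constant" in row["note"]

    def test_empty_stratum_raises(self, default_cohort):
        recs, _ = default_cohort
        # force everyone AKI-negative so the grouping has a single stratum
        flat = [ParticipantRecord(**{**r.__dict__, "cr0": 0.9, "cr48": 0.9, "cr3m": 0.9})
                for r in recs]
        with pytest.raises(DomainError, match="strata"):
            analysis.compare_groups(flat)

    def test_comparison_table_runs_on_cohort(self, default_cohort):
        recs, _ = default_cohort
        out = analysis.compare_groups(recs)
        tested = out[out["test"] != "skipped"]
        assert {"age", "hiv"} <= set(tested["variable"])
        assert ((tested["p"] >= 0) & (tested["p"] <= 1)).all()


class TestSplineBasis:
    def test_linear_beyond_boundary_knots(self):
        knots = (25.0, 40.0, 60.0)
        x = np.array([70.0, 80.0, 90.0])
        basis = analysis.natural_spline_basis(x, knots)
        slopes = np.diff(basis[:, 1]) / np.diff(x)
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-9)
        below = analysis.natural_spline_basis(np.array([5.0, 15.0]), knots)
        assert below[:, 1] == pytest.approx(0.0)

    def test_bad_knots_rejected(self):
        with pytest.raises(DomainError):
            analysis.natural_spline_basis([1.0], (40.0, 40.0, 60.0))


class TestLogistic:
    def test_duplicated_dataset_identical_estimates(self, default_cohort):
        recs, _ = default_cohort
        fit1 = analysis.fit_aki_logistic(recs)
        fit2 = analysis.fit_aki_logistic(list(recs) + list(recs))
        assert np.allclose(fit1.result.params.values, fit2.result.params.values,
                           atol=1e-6)

    def test_fit_reproducible(self, default_cohort):
        recs, _ = default_cohort
        a = analysis.fit_aki_logistic(recs).result.params.values
        b = analysis.fit_aki_logistic(recs).result.params.values
        assert np.allclose(a, b, atol=1e-8)

    def test_unadjusted_returns_per_covariate_fits(self, default_cohort):
        recs, _ = default_cohort
        fits = analysis.fit_aki_logistic(recs, adjusted=False)
        assert "hiv" in fits and "dbp" in fits
        assert fits["hiv"].params.shape == (2,)

    def test_age_hiv_covariate_set(self, default_cohort):
        recs, _ = default_cohort
        fit = analysis.fit_aki_logistic(recs, covariate_set="age_hiv")
        assert fit.covariates == ("hiv",)
        assert "qsofa" not in fit.result.params.index


class TestORCurve:
    def test_reference_age_is_unity_with_degenerate_ci(self, default_cohort):
        recs, _ = default_cohort
        fit = analysis.fit_aki_logistic(recs)
        curve = analysis.age_or_curve(fit, replicates=60, seed=1)
        i = list(curve.ages).index(40.0)
        assert curve.odds_ratio[i] == 1.0
        assert curve.ci_low[i] == 1.0 and curve.ci_high[i] == 1.0

    def test_same_seed_identical_cis(self, default_cohort):
        recs, _ = default_cohort
        fit = analysis.fit_aki_logistic(recs)
        c1 = analysis.age_or_curve(fit, replicates=60, seed=9)
        c2 = analysis.age_or_curve(fit, replicates=60, seed=9)
        assert np.array_equal(c1.ci_low, c2.ci_low)
        assert np.array_equal(c1.ci_high, c2.ci_high)

    def test_designed_age_effect_is_monotone(self):
        recs, _ = synth.generate_cohort(synth.paper_default_config(n=4000, seed=21))
        fit = analysis.fit_aki_logistic(recs)
        curve = analysis.age_or_curve(fit, ages=(40, 50, 60), replicates=40, seed=2)
        or50, or60 = curve.odds_ratio[1], curve.odds_ratio[2]
        assert or60 > or50 > 1.0

    def test_ci_width_shrinks_with_n(self):
        widths = {}
        for n, seed in ((101, 31), (4000, 32)):
            recs, _ = synth.generate_cohort(synth.paper_default_config(n=n, seed=seed))
            fit = analysis.fit_aki_logistic(recs)
            curve = analysis.age_or_curve(fit, ages=(20, 30, 50, 60, 70),
                                          replicates=120, seed=3)
            widths[n] = np.median(np.log(curve.ci_high) - np.log(curve.ci_low))
        assert widths[4000] < widths[101]


class TestSurvival:
    def test_km_monotone_from_one(self, default_cohort):
        recs, _ = default_cohort
        fit = analysis.fit_survival(recs, exposure="hiv")
        for curve in fit.km.values():
            s = curve["survival"].values
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()

    def test_event_free_cohort_refused(self, default_cohort):
        recs, _ = default_cohort
        alive = [ParticipantRecord(**{**r.__dict__, "died": False}) for r in recs]
        with pytest.raises(DomainError, match="no deaths"):
            analysis.fit_survival(alive, exposure="hiv")

    def test_hr_confidence_interval_brackets_estimate(self, default_cohort):
        recs, _ = default_cohort
        fit = analysis.fit_survival(recs, exposure="hiv")
        assert fit.ci_low <= fit.hazard_ratio <= fit.ci_high

    def test_aki_exposure_supported(self, default_cohort):
        recs, _ = default_cohort
        fit = analysis.fit_survival(recs, exposure="aki")
        assert fit.hazard_ratio > 0


class TestPower:
    def spec(self, **kw):
        base = dict(n1=35, n2=53, p1=0.23)
        base.update(kw)
        return analysis.PowerSpec(**base)

    def test_solver_hits_requested_power(self):
        for method in analysis.POWER_METHODS:
            or_ = analysis.minimal_detectable_or(self.spec(), method=method)
            p2 = 1 / (1 + (1 - 0.23) / (0.23 * or_))
            assert analysis.attained_power(self.spec(), p2, method) == pytest.approx(
                0.80, abs=1e-6)

    def test_or_approaches_one_as_power_approaches_alpha(self):
        near_null = analysis.minimal_detectable_or(
            self.spec(alpha=0.05, power=0.051), method="z_unpooled")
        assert 1.0 < near_null < 1.35

    def test_strictly_decreasing_in_sample_size(self):
        small = analysis.minimal_detectable_or(self.spec())
        large = analysis.minimal_detectable_or(self.spec(n1=70, n2=106))
        assert large < small

    def test_decreasing_as_power_loosens(self):
        strict = analysis.minimal_detectable_or(self.spec(power=0.9))
        loose = analysis.minimal_detectable_or(self.spec(power=0.6))
        assert loose < strict

    def test_unattainable_power_raises(self):
        with pytest.raises(DomainError, match="power"):
            analysis.minimal_detectable_or(
                analysis.PowerSpec(n1=3, n2=3, p1=0.5, power=0.99))

    def test_invalid_spec_rejected(self):
        with pytest.raises(DomainError):
            analysis.PowerSpec(n1=35, n2=53, p1=1.2)
        with pytest.raises(DomainError):
            analysis.PowerSpec(n1=35, n2=53, p1=0.2, alpha=0.9, power=0.8)


class TestOutcomeTable:
    def test_denominator_logic(self, default_cohort):
        recs, _ = default_cohort
        tab = analysis.outcome_table(recs).set_index("label")
        n = len(recs)
        assert (tab["denominator"] <= n).all()
        assert tab.loc["AKI (MDRD_G100)", "denominator"] == n
        contactable = sum(r.died is not None for r in recs)
        assert tab.loc["Alive at 3 months", "denominator"] == contactable
        surv3m = sum(r.died is False and r.cr3m is not None for r in recs)
        assert tab.loc["CKD", "denominator"] == surv3m

    def test_empty_cohort_rejected(self):
        with pytest.raises(DomainError):
            analysis.outcome_table([])
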