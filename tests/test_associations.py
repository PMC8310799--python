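"""Trait preprocessing, regression, HWE testing and contingency summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from milkmr.associations import (
    AssociationEstimate,
    GeneticCoding,
    TraitConfig,
    adjust_biomarker,
    adjust_blood_pressure,
    code_genotypes,
    contingency_summary,
    hwe_test,
    inverse_normal_transform,
    linear_association,
    logistic_association,
    pulse_pressure,
)
from milkmr.exceptions import DegenerateFitError, ValidationError


class TestMedicationCorrections:
    def test_bp_correction_applied(self):
        assert adjust_blood_pressure(140, 90, True) == (155.0, 100.0)

    def test_bp_identity_untreated(self):
        assert adjust_blood_pressure(140, 90, False) == (140.0, 90.0)

    def test_bp_rejects_inverted_pressures(self):
        with pytest.raises(ValidationError):
            adjust_blood_pressure(120, 130, True)

    @pytest.mark.parametrize(
        "trait,value,expected",
        [("ldl_c", 3.40, 5.00), ("crp", 2.42, 2.00), ("hdl_c", 2.10, 2.0),
         ("total_cholesterol", 4.50, 6.0), ("triglycerides", 1.74, 2.0),
         ("hba1c", 5.20, 5.0)],
    )
    def test_biomarker_division_factors(self, trait, value, expected):
        assert adjust_biomarker(value, trait, True) == pytest.approx(expected)

    def test_biomarker_identity_untreated(self):
        assert adjust_biomarker(3.4, "ldl_c", False) == 3.4

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValidationError):
            adjust_biomarker(1.0, "ferritin", True)

    def test_pulse_pressure(self):
        assert pulse_pressure(155, 100) == 55.0
        assert pulse_pressure(120, 80) == 40.0
        with pytest.raises(ValidationError):
            pulse_pressure(80, 80)


class TestTraitConfig:
    def test_add_constant_restricted_to_bp(self):
        with pytest.raises(ValidationError):
            TraitConfig(name="ldl_c", medication_rule="add_constant")

    def test_sd_scale_requires_transform(self):
        with pytest.raises(ValidationError):
            TraitConfig(name="bmi", scale="sd_transformed", transform=False)

    def test_mmhg_untransformed_by_default(self):
        cfg = TraitConfig(name="sbp", scale="mmHg", medication_rule="add_constant")
        assert cfg.transform is False

    def test_factor_autofilled(self):
        cfg = TraitConfig(name="crp", medication_rule="divide_by_factor")
        assert cfg.factor == 1.21


class TestInverseNormalTransform:
    def test_blom_quantiles_n3(self):
        out = inverse_normal_transform([10.0, 20.0, 30.0])
        expected = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected)
        assert out[1] == 0.0

    def test_rank_invariance_under_monotone_relabeling(self):
        x = np.array([3.0, 1.0, 7.0, 2.5, 9.0])
        np.testing.assert_allclose(inverse_normal_transform(x),
                                   inverse_normal_transform(np.exp(x)))

    def test_ties_share_value(self):
        out = inverse_normal_transform([1.0, 5.0, 5.0, 9.0])
        assert out[1] == out[2]

    def test_moments(self):
        rng = np.random.default_rng(0)
        out = inverse_normal_transform(rng.gamma(2, 2, size=500))
        assert abs(out.mean()) < 1e-10
        assert 0.9 <= out.var() <= 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            inverse_normal_transform([2.0, 2.0, 2.0])


class TestGeneticCoding:
    def test_recessive_carrier_mapping(self):
        np.testing.assert_array_equal(
            code_genotypes([0, 1, 2], GeneticCoding.RECESSIVE_CARRIER), [0, 1, 1]
        )

    def test_additive_identity(self):
        np.testing.assert_array_equal(code_genotypes([0, 1, 2], GeneticCoding.ADDITIVE),
                                      [0, 1, 2])

    def test_bad_dosage_rejected(self):
        with pytest.raises(ValidationError):
            code_genotypes([0, 3], GeneticCoding.ADDITIVE)


class TestLinearAssociation:
    def test_perfect_fit_rejected(self):
        g = np.tile([0.0, 1.0, 2.0], 10)
        with pytest.raises(DegenerateFitError):
            linear_association(2.0 * g, g)

    def test_covariate_shift_invariance(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.5, 500).astype(float)
        cov = rng.normal(size=500)
        y = 0.3 * g + 0.5 * cov + rng.normal(size=500)
        a = linear_association(y, g, covariates={"c": cov})
        b = linear_association(y, g, covariates={"c": cov + 100.0})
        assert a.beta == pytest.approx(b.beta, rel=1e-9)
        assert a.se == pytest.approx(b.se, rel=1e-9)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.5, 100).astype(float)
        y = rng.normal(size=100)
        with pytest.raises(DegenerateFitError, match="dup"):
            linear_association(y, g, covariates={"dup": g})

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        n, reps = 10_000, 1000
        rejections = 0
        for _ in range(reps):
            g = rng.binomial(2, 0.759, n).astype(float)
            y = rng.standard_normal(n)
            if linear_association(y, g).p < 0.05:
                rejections += 1
        assert 0.036 <= rejections / reps <= 0.064

    def test_effect_recovery_at_scale(self):
        rng = np.random.default_rng(4)
        n = 375_000
        g = rng.binomial(2, 0.759, n).astype(float)
        y = 0.014 * g + rng.standard_normal(n)
        est = linear_association(y, g)
        assert abs(est.beta - 0.014) < 3 * est.se


class TestLogisticAssociation:
    @staticmethod
    def _expand(a, b, c, d):
        """2x2 table: rows exposure 0/1, cols outcome 0/1 with counts a,b,c,d."""
        x = np.concatenate([np.zeros(a + b), np.ones(c + d)])
        y = np.concatenate([np.zeros(a), np.ones(b), np.zeros(c), np.ones(d)])
        return y, x

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_cross_product_odds_ratio(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(20, 400, size=4)
        y, x = self._expand(a, b, c, d)
        est = logistic_association(y, x)
        assert est.beta == pytest.approx(np.log((a * d) / (b * c)), abs=1e-6)

    def test_uk_biobank_recessive_milk_or(self):
        # carriers vs CC: unadjusted cross-product OR from the printed counts
        y, x = self._expand(2090, 20820, 28395, 339126)
        est = logistic_association(y, x, coding=GeneticCoding.RECESSIVE_CARRIER,
                                   trait="milk_drinker")
        or_closed = (339126 / 28395) / (20820 / 2090)
        assert np.exp(est.beta) == pytest.approx(or_closed, abs=1e-6)
        assert np.exp(est.beta) == pytest.approx(1.199, abs=0.001)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(DegenerateFitError):
            logistic_association(np.ones(50), np.arange(50, dtype=float) % 3)

    def test_separated_predictor_rejected(self):
        y = np.concatenate([np.zeros(30), np.ones(30)])
        x = y.copy()
        with pytest.raises((DegenerateFitError, Exception)):
            logistic_association(y, x)


class TestHWE:
    def test_exact_equilibrium(self):
        res = hwe_test(25, 50, 25)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        res = hwe_test(30, 40, 30)
        assert res.chi_square == pytest.approx(4.0)
        assert res.p == pytest.approx(0.0455, abs=2e-4)

    def test_monomorphic_sample(self):
        res = hwe_test(0, 0, 100)
        assert res.chi_square == 0.0 and res.p == 1.0

    def test_allele_label_swap_invariance(self):
        a = hwe_test(12, 47, 41)
        b = hwe_test(41, 47, 12)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            hwe_test(-1, 5, 5)


class TestContingency:
    def test_uk_biobank_tt_row(self):
        t = contingency_summary([[17287, 207963]], row_labels=["TT"],
                                col_labels=["never", "drinker"])
        assert t.row_percentages.loc["TT", "drinker"] == 92.33

    def test_1958bc_women_row(self):
        t = contingency_summary([[855, 1636]], row_labels=["women"],
                                col_labels=["never", "drinker"])
        assert t.row_percentages.loc["women", "never"] == 34.32

    def test_single_cell_normalization(self):
        t = contingency_summary([[42]])
        assert t.row_percentages.iloc[0, 0] == 100.00

    def test_row_percentages_sum_to_100(self):
        t = contingency_summary([[10, 20, 30], [5, 5, 5]])
        np.testing.assert_allclose(t.row_percentages.sum(axis=1), 100.0, atol=0.02)

    def test_independence_chi_square_attached(self):
        t = contingency_summary([[917, 2110], [657, 1397], [127, 234]])
        assert t.df == 2 and t.chi_square > 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            contingency_summary(np.empty((0, 0)))


def test_estimate_p_consistent_with_wald():
    est = AssociationEstimate("s", "t", "genetic", beta=0.1, se=0.05)
    assert est.p == pytest.approx(2 * stats.norm.sf(2.0))
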