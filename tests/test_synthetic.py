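"""Cohort simulator: HWE sampling, milk model, outcomes, two-sample split."""

import numpy as np
import pandas as pd
import pytest

from milkmr.associations import hwe_test, linear_association
from milkmr.exceptions import ValidationError
from milkmr.synthetic import (
    MedicationModel,
    SimulationScenario,
    make_two_sample_setting,
    sample_genotypes,
    simulate_cohort,
    simulate_milk_intake,
    simulate_outcomes,
)


class TestSampleGenotypes:
    def test_degenerate_frequency_gives_all_homozygotes(self):
        assert np.all(sample_genotypes(10, 1.0, seed=1) == 2)

    def test_tt_fraction_matches_hwe_expectation(self):
        # T-allele frequency as in a UK-Biobank-scale sample
        p = 0.759
        n = 100_000
        g = sample_genotypes(n, p, seed=3)
        expected_tt = p**2
        sd = np.sqrt(expected_tt * (1 - expected_tt) / n)
        assert abs(np.mean(g == 2) - expected_tt) < 4 * sd
        # and CC/CT classes too
        assert abs(np.mean(g == 0) - (1 - p) ** 2) < 4 * np.sqrt((1 - p) ** 2 / n)

    def test_seed_determinism(self):
        a = sample_genotypes(3, 0.5, seed=7)
        b = sample_genotypes(3, 0.5, seed=7)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_frequency_rejected(self, bad):
        with pytest.raises(ValidationError):
            sample_genotypes(10, bad, seed=0)

    def test_hwe_holds_across_replicates(self):
        # chi-square HWE test non-significant at alpha=0.001 in >=99% of draws
        rejections = 0
        for i in range(1000):
            g = sample_genotypes(500, 0.7, seed=10_000 + i)
            counts = np.bincount(g, minlength=3)
            if hwe_test(*counts).p < 0.001:
                rejections += 1
        assert rejections <= 10


class TestMilkIntake:
    def test_null_per_allele_effect(self):
        sc = SimulationScenario(n_individuals=50_000, per_allele_milk_effect=0.0,
                                milk_baseline=300.0, seed=5)
        g = sample_genotypes(sc.n_individuals, sc.t_allele_freq, seed=5)
        milk = simulate_milk_intake(g, sc)
        est = linear_association(milk, g, kind="genetic", trait="milk")
        assert abs(est.beta) < 3 * est.se

    def test_per_allele_effect_recovery(self):
        sc = SimulationScenario(n_individuals=200_000, per_allele_milk_effect=17.5,
                                milk_baseline=300.0, seed=6)
        g = sample_genotypes(sc.n_individuals, sc.t_allele_freq, seed=6)
        milk = simulate_milk_intake(g, sc)
        est = linear_association(milk, g, kind="genetic", trait="milk")
        assert abs(est.beta - 17.5) < 3 * est.se

    def test_noise_free_closed_form(self):
        sc = SimulationScenario(n_individuals=9, per_allele_milk_effect=20.0,
                                milk_baseline=150.0, milk_sd=1e-12, seed=0)
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2])
        milk = simulate_milk_intake(g, sc)
        np.testing.assert_allclose(milk, 150.0 + 20.0 * g, atol=1e-6)

    def test_truncation_at_zero(self):
        sc = SimulationScenario(n_individuals=2_000, milk_baseline=5.0,
                                per_allele_milk_effect=0.0, milk_sd=50.0, seed=8)
        g = sample_genotypes(2_000, 0.5, seed=8)
        assert np.min(simulate_milk_intake(g, sc)) >= 0.0

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            SimulationScenario(milk_sd=-1.0)


class TestOutcomes:
    def test_full_null_genetic_association(self):
        sc = SimulationScenario(n_individuals=50_000, causal_effect_per_gram=0.0,
                                direct_genetic_effect=0.0, seed=9)
        cohort = simulate_cohort(sc)
        est = linear_association(cohort["outcome"], cohort["genotype"], trait="outcome")
        assert abs(est.beta) < 3 * est.se

    def test_binary_prevalence_calibration(self):
        sc = SimulationScenario(n_individuals=50_000, causal_effect_per_gram=0.0,
                                binary_baseline_prevalence=0.1, seed=10)
        cohort = simulate_cohort(sc)
        prev = cohort["disease"].mean()
        sd = np.sqrt(0.1 * 0.9 / len(cohort))
        assert abs(prev - 0.1) < 4 * sd

    def test_medication_by_indication(self):
        # treated individuals have higher underlying pressure on average
        sc = SimulationScenario(n_individuals=20_000, seed=11)
        cohort = simulate_cohort(sc)
        df = cohort.data
        treated = df[df.bp_medication == 1]
        untreated = df[df.bp_medication == 0]
        assert len(treated) > 100
        # stored values are on-treatment: adding 15 back shifts treated above untreated
        assert treated.sbp.mean() + 15 > untreated.sbp.mean()

    def test_unknown_trait_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            small_cohort.outcome("nonexistent_trait")

    def test_length_mismatch_rejected(self, small_scenario):
        with pytest.raises(ValidationError):
            simulate_outcomes([0, 1, 2], [100.0], small_scenario)


class TestTwoSampleSetting:
    def test_stream_separation_and_reproducibility(self):
        sc = SimulationScenario(n_individuals=2_000, seed=12)
        exp1, out1 = make_two_sample_setting(sc)
        exp2, out2 = make_two_sample_setting(sc)
        pd.testing.assert_frame_equal(exp1.data, exp2.data)
        pd.testing.assert_frame_equal(out1.data, out2.data)
        assert not np.array_equal(exp1["milk"].to_numpy(), out1["milk"].to_numpy())

    def test_zero_n_rejected(self):
        with pytest.raises(ValidationError):
            SimulationScenario(n_individuals=0)

    def test_cohort_determinism(self):
        sc = SimulationScenario(n_individuals=1_000, seed=13)
        pd.testing.assert_frame_equal(simulate_cohort(sc).data, simulate_cohort(sc).data)


def test_confounding_biases_phenotypic_not_genetic():
    """With U -> milk and U -> outcome and zero causal effect, the
    observational milk-outcome regression is biased while the genetic
    association stays null."""
    sc = SimulationScenario(
        n_individuals=200_000, causal_effect_per_gram=0.0,
        confounder_effect_on_milk=40.0, confounder_effect_on_outcome=0.5, seed=14,
    )
    cohort = simulate_cohort(sc)
    phen = linear_association(cohort["outcome"], cohort["milk"], kind="phenotypic")
    gen = linear_association(cohort["outcome"], cohort["genotype"], kind="genetic")
    assert abs(phen.beta) > 5 * phen.se
    assert abs(gen.beta) < 3 * gen.se


def test_medication_model_probability_monotone():
    m = MedicationModel(midpoint=150.0, slope=0.1, max_prob=0.8)
    p = m.probability([120.0, 150.0, 180.0])
    assert np.all(np.diff(p) > 0) and p[1] == pytest.approx(0.4)
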