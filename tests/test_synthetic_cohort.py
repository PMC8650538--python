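"""Planted frequency tables, HWE genotypes, phenotype marginals, disease model."""

import collections
import math

import numpy as np
import pytest
from scipy.special import logit
from scipy.stats import chisquare

from cadpop.io_formats import ValidationError
from cadpop.grs_engine import compute_scores, impute_missing
from cadpop.synthetic_cohort import (
    ENGLAND,
    SCOTLAND,
    CohortConfig,
    DiseaseModel,
    PopulationFreqTable,
    calibrate_intercept,
    generate_cohort,
    make_frequency_table,
    make_weights,
    simulate_disease,
    simulate_genotypes,
    simulate_phenotypes,
)
from dataclasses import replace


class TestFrequencyTable:
    def test_planted_split_is_exact(self):
        ft = make_frequency_table(163, 37, 35, 0.02, (0.1, 0.9), seed=11)
        counts = collections.Counter(ft.planted_direction)
        assert counts == {"null": 91, "higher_A": 37, "higher_B": 35}

    def test_zero_delta_all_null(self):
        ft = make_frequency_table(20, 5, 5, 0.0, (0.1, 0.9), seed=1)
        assert set(ft.planted_direction) == {"null"}
        np.testing.assert_array_equal(ft.raf_a, ft.raf_b)

    def test_max_planted_difference_equals_delta(self):
        ft = make_frequency_table(10, 5, 5, 0.033, (0.1, 0.9), seed=2)
        assert np.abs(ft.raf_a - ft.raf_b).max() == pytest.approx(0.033)

    def test_delta_range_spans_requested_band(self):
        ft = make_frequency_table(200, 100, 100, (0.003, 0.033), (0.2, 0.8), seed=3)
        diffs = np.abs(ft.raf_a - ft.raf_b)
        assert diffs.min() >= 0.003 and diffs.max() <= 0.033

    def test_infeasible_delta_names_variant(self):
        with pytest.raises(ValidationError, match="rs"):
            make_frequency_table(10, 5, 5, 0.5, (0.55, 0.6), seed=4)

    def test_direction_consistency_enforced(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            PopulationFreqTable(["v0"], [0.3], [0.4], ["higher_A"])

    def test_deterministic_given_seed(self):
        a = make_frequency_table(50, 10, 10, 0.02, (0.1, 0.9), seed=9)
        b = make_frequency_table(50, 10, 10, 0.02, (0.1, 0.9), seed=9)
        np.testing.assert_array_equal(a.raf_b, b.raf_b)
        assert a.planted_direction == b.planted_direction


class TestGenotypes:
    def test_fixed_allele_gives_homozygotes(self):
        m = simulate_genotypes([1.0], 200, ["v0"], seed=0)
        assert (m.dosages == 2).all()

    def test_empirical_raf_within_binomial_tolerance(self):
        n = 10_000
        m = simulate_genotypes([0.5], n, ["v0"], seed=1)
        raf = m.dosages.mean() / 2
        assert abs(raf - 0.5) < 3 * math.sqrt(0.25 / (2 * n))

    def test_hwe_genotype_class_proportions(self):
        """Genotype classes at p=0.3 follow (1-p)^2 : 2p(1-p) : p^2."""
        p, n = 0.3, 50_000
        m = simulate_genotypes([p], n, ["v0"], seed=2)
        obs = [(m.dosages == g).sum() for g in (0, 1, 2)]
        exp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2]) * n
        assert chisquare(obs, exp).pvalue > 0.001

    def test_missing_rate_applied(self):
        m = simulate_genotypes([0.4] * 50, 2000, [f"v{i}" for i in range(50)],
                               missing_rate=0.05, seed=3)
        assert np.isnan(m.dosages).mean() == pytest.approx(0.05, abs=0.005)

    def test_bad_missing_rate_rejected(self):
        with pytest.raises(ValidationError):
            simulate_genotypes([0.5], 10, ["v0"], missing_rate=1.0)


class TestPhenotypes:
    def test_population_marginals_match_profile(self):
        df = simulate_phenotypes(100_000, ENGLAND, seed=4)
        assert df["age"].mean() == pytest.approx(56.7, abs=0.1)
        assert df["smoker"].mean() == pytest.approx(0.102, abs=0.005)
        assert df["sbp"].mean() == pytest.approx(138.0, abs=0.3)
        assert df["sex"].eq("F").mean() == pytest.approx(0.534, abs=0.006)

    def test_second_population_profile(self):
        df = simulate_phenotypes(100_000, SCOTLAND, seed=5)
        assert df["smoker"].mean() == pytest.approx(0.128, abs=0.004)
        assert df["diabetic"].mean() == pytest.approx(0.060, abs=0.003)

    def test_zero_sd_collapses_to_mean(self):
        prof = replace(ENGLAND, age=(56.7, 0.0))
        df = simulate_phenotypes(100, prof, seed=6)
        assert (df["age"] == 56.7).all()

    def test_bounds_respected(self):
        df = simulate_phenotypes(50_000, ENGLAND, seed=7)
        for col in ("age", "bmi", "sbp", "tc", "hdl"):
            lo, hi = ENGLAND.bounds[col]
            assert df[col].between(lo, hi).all()

    def test_bad_rate_rejected(self):
        with pytest.raises(ValidationError):
            replace(ENGLAND, smoker_rate=1.2)


class TestDiseaseModel:
    def test_calibrated_prevalence_hits_target(self):
        n = 50_000
        df = simulate_phenotypes(n, ENGLAND, seed=8)
        wgrs = np.random.default_rng(8).normal(10.6, 0.5, n)
        model = DiseaseModel(beta_grs=0.0, target_prevalence=0.0768)
        cad, alpha = simulate_disease(wgrs, df, model, seed=8)
        se = math.sqrt(0.0768 * 0.9232 / n)
        assert cad.mean() == pytest.approx(0.0768, abs=3 * se)
        assert alpha == pytest.approx(logit(0.0768), abs=1e-6)  # betas all zero

    def test_symmetric_intercept_gives_half(self):
        n = 20_000
        df = simulate_phenotypes(n, ENGLAND, seed=9)
        model = DiseaseModel(beta_grs=0.0, intercept=float(logit(0.5)))
        cad, _ = simulate_disease(np.zeros(n), df, model, seed=9)
        assert cad.mean() == pytest.approx(0.5, abs=3 * math.sqrt(0.25 / n))

    def test_positive_genetic_effect_separates_cases(self):
        n = 50_000
        df = simulate_phenotypes(n, ENGLAND, seed=10)
        wgrs = np.random.default_rng(10).normal(10.6, 0.5, n)
        model = DiseaseModel(beta_grs=1.0, target_prevalence=0.08)
        cad, _ = simulate_disease(wgrs, df, model, seed=10)
        assert wgrs[cad].mean() > wgrs[~cad].mean()

    def test_nonbracketing_calibration_suggests_wider_bounds(self):
        with pytest.raises(ValidationError, match="widen"):
            calibrate_intercept(np.zeros(100), 0.5, bounds=(5.0, 10.0))

    def test_model_needs_intercept_or_target(self):
        with pytest.raises(ValidationError):
            DiseaseModel(beta_grs=0.1)

    def test_logistic_fit_recovers_genetic_effect(self):
        """A logistic regression on simulated cohorts recovers the
        planted wGRS coefficient within 3 standard errors."""
        import statsmodels.api as sm

        beta_true, n = 0.8, 50_000
        hits = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            wgrs = rng.normal(10.6, 0.5, n)
            df = simulate_phenotypes(n, ENGLAND, seed=200 + r)
            model = DiseaseModel(beta_grs=beta_true, target_prevalence=0.0768)
            cad, _ = simulate_disease(wgrs, df, model, seed=300 + r)
            X = sm.add_constant(wgrs - wgrs.mean())
            fit = sm.Logit(cad.astype(float), X).fit(disp=0)
            if abs(fit.params[1] - beta_true) < 3 * fit.bse[1]:
                hits += 1
        assert hits >= 18  # ~99.7% coverage per replicate


class TestWholeCohort:
    def test_generation_reproducible_bit_for_bit(self):
        cfg = CohortConfig(n_a=800, n_b=200, n_variants=30, n_higher_a=6, n_higher_b=5)
        c1 = generate_cohort(cfg, seed=21)
        c2 = generate_cohort(cfg, seed=21)
        la = c1.freq_table.label_a
        np.testing.assert_array_equal(c1.genotypes[la].dosages, c2.genotypes[la].dosages)
        assert c1.phenotypes.equals(c2.phenotypes)
        assert c1.intercepts == c2.intercepts

    def test_different_seeds_differ(self):
        cfg = CohortConfig(n_a=300, n_b=100, n_variants=10, n_higher_a=2, n_higher_b=2)
        c1 = generate_cohort(cfg, seed=1)
        c2 = generate_cohort(cfg, seed=2)
        la = c1.freq_table.label_a
        assert not np.array_equal(c1.genotypes[la].dosages, c2.genotypes[la].dosages)

    def test_empirical_rafs_converge_to_planted(self):
        """At n = 100,000 and delta >= 0.01 every planted direction matches
        the sign of the empirical frequency difference."""
        ft = make_frequency_table(40, 10, 10, 0.015, (0.2, 0.8), seed=30)
        ma = simulate_genotypes(ft.raf_a, 100_000, ft.variant_ids, seed=31)
        mb = simulate_genotypes(ft.raf_b, 100_000, ft.variant_ids, seed=32)
        emp_a = ma.dosages.mean(axis=0) / 2
        emp_b = mb.dosages.mean(axis=0) / 2
        se = 3 * np.sqrt(ft.raf_a * (1 - ft.raf_a) / (2 * 100_000))
        np.testing.assert_array_less(np.abs(emp_a - ft.raf_a), se)
        for d, ea, eb in zip(ft.planted_direction, emp_a, emp_b):
            if d == "higher_A":
                assert ea > eb
            elif d == "higher_B":
                assert eb > ea
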