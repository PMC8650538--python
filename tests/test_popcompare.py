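"""Two-sample tests and the risk-allele-frequency scan."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cadpop.io_formats import ValidationError
from cadpop.popcompare import (
    af_scan,
    chi2_two_by_two,
    dumbbell_table,
    ks_two_sample,
    mannwhitney,
    prevalence_table,
    summarize_scan,
    welch_ttest,
)
from cadpop.synthetic_cohort import make_frequency_table, simulate_genotypes

from conftest import make_matrix


class TestChi2:
    def test_published_sex_counts_reproduce_printed_p(self):
        """Pearson chi-squared on the two populations' female/male counts."""
        res = chi2_two_by_two([[169_679, 148_210], [17_411, 14_552]])
        assert round(res.p_value, 4) == 0.0002
        assert res.df == 1

    def test_identical_proportions_null(self):
        res = chi2_two_by_two([[30, 70], [60, 140]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError, match="marginal"):
            chi2_two_by_two([[0, 5], [0, 7]])

    def test_agrees_with_permutation_oracle(self):
        """Asymptotic p on a 3/7 vs 5/5 table vs a 1e5-draw label-shuffle
        oracle (hypergeometric resampling of the first row total)."""
        table = np.array([[3, 7], [5, 5]])
        obs = chi2_two_by_two(table).statistic
        rng = np.random.default_rng(2024)
        n_draws = 100_000
        a = rng.hypergeometric(ngood=8, nbad=12, nsample=10, size=n_draws)
        stats_perm = np.empty(n_draws)
        for i, ai in enumerate(a):
            t = np.array([[ai, 10 - ai], [8 - ai, 2 + ai]], dtype=float)
            n = t.sum()
            stats_perm[i] = n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2 / (
                t[0].sum() * t[1].sum() * t[:, 0].sum() * t[:, 1].sum())
        p_incl = float((stats_perm >= obs - 1e-9).mean())   # P(stat >= obs)
        p_strict = float((stats_perm > obs + 1e-9).mean())  # P(stat > obs)
        p_asym = chi2_two_by_two(table).p_value
        # the statistic is discrete here, so the continuous chi-squared p
        # must fall between the strict and inclusive permutation tails
        se = math.sqrt(0.25 / n_draws)
        assert p_strict - 3 * se <= p_asym <= p_incl + 3 * se
        assert p_incl > p_strict  # the observed value carries real mass

    def test_equals_squared_pooled_z(self):
        """Uncorrected Pearson chi-squared is the squared two-proportion
        pooled z statistic."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n1, n2 = rng.integers(20, 500, size=2)
            x1, x2 = rng.integers(1, n1), rng.integers(1, n2)
            p_pool = (x1 + x2) / (n1 + n2)
            z = (x1 / n1 - x2 / n2) / math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
            res = chi2_two_by_two([[x1, n1 - x1], [x2, n2 - x2]])
            assert res.statistic == pytest.approx(z ** 2, rel=1e-10)


class TestTwoSampleTests:
    def test_identical_samples_are_null(self):
        x = np.arange(50, dtype=float)
        assert welch_ttest(x, x).statistic == 0.0
        assert welch_ttest(x, x).p_value == pytest.approx(1.0)
        assert ks_two_sample(x, x).statistic == 0.0

    def test_power_at_huge_effect(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.0, 1.0, 5000)
        y = rng.normal(0.5, 1.0, 5000)
        assert welch_ttest(x, y).p_value < 1e-6
        assert mannwhitney(x, y).p_value < 1e-6
        assert ks_two_sample(x, y).p_value < 1e-6

    def test_welch_null_pvalues_uniform(self):
        """Type-I calibration: 1,000 null replicates give uniform p-values."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1000, 40))
        y = rng.normal(size=(1000, 40))
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        assert stats.kstest(res.pvalue, "uniform").pvalue > 0.01
        # the vectorized null replicates match the module's scalar route
        single = welch_ttest(x[0], y[0])
        assert single.p_value == pytest.approx(res.pvalue[0], rel=1e-12)

    def test_total_tie_mannwhitney_warns_not_crashes(self):
        with pytest.warns(UserWarning, match="tied"):
            res = mannwhitney(np.ones(10), np.ones(12))
        assert res.p_value == 1.0

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            welch_ttest(np.array([1.0]), np.array([1.0, 2.0]))


class TestAfScan:
    def test_identical_matrices_nothing_significant(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(300, 20)).astype(float)
        m = make_matrix(d)
        scan = af_scan(m, make_matrix(d.copy(), sample_prefix="t"))
        assert (scan["diff"] == 0).all()
        assert not scan["significant"].any()
        assert (scan["p_adj"] >= scan["p_raw"]).all()

    def test_large_frequency_gap_significant_after_bonferroni(self):
        """A 21.0% vs 17.6% frequency difference at the full two-cohort
        sample sizes is significant among 163 Bonferroni-corrected tests."""
        def column(n, raf):
            risk = round(2 * n * raf)
            col = np.zeros(n)
            col[: risk // 2] = 2
            if risk % 2:
                col[risk // 2] = 1
            return col.reshape(-1, 1)

        ma = make_matrix(column(317_889, 0.210), sample_prefix="a")
        mb = make_matrix(column(31_963, 0.176), sample_prefix="b")
        scan = af_scan(ma, mb)
        row = scan.iloc[0]
        assert row["raf_a"] == pytest.approx(0.210, abs=1e-4)
        assert row["direction"] == "higher_A"
        # Bonferroni over the full 163-SNP panel still leaves it significant
        assert min(1.0, 163 * row["p_raw"]) < 0.001

    def test_direction_antisymmetric_under_population_swap(self):
        ft = make_frequency_table(30, 8, 7, 0.05, (0.2, 0.8), seed=7)
        ma = simulate_genotypes(ft.raf_a, 20_000, ft.variant_ids, seed=8)
        mb = simulate_genotypes(ft.raf_b, 20_000, ft.variant_ids, seed=9)
        fwd = af_scan(ma, mb)
        rev = af_scan(mb, ma)
        flip = {"higher_A": "higher_B", "higher_B": "higher_A", "none": "none"}
        assert [flip[d] for d in fwd["direction"]] == list(rev["direction"])
        np.testing.assert_allclose(fwd["chi2"], rev["chi2"], rtol=1e-12)

    def test_monomorphic_variant_row_emitted(self):
        ma = make_matrix(np.full((50, 1), 2.0), sample_prefix="a")
        mb = make_matrix(np.full((60, 1), 2.0), sample_prefix="b")
        scan = af_scan(ma, mb)
        assert scan["p_raw"].iloc[0] == 1.0
        assert scan["direction"].iloc[0] == "none"
        assert not scan["significant"].iloc[0]

    def test_matches_scalar_chi2_route(self):
        rng = np.random.default_rng(10)
        ma = make_matrix(rng.integers(0, 3, size=(500, 10)).astype(float), sample_prefix="a")
        mb = make_matrix(rng.integers(0, 3, size=(400, 10)).astype(float), sample_prefix="b")
        scan = af_scan(ma, mb)
        for j in range(10):
            ra = np.nansum(ma.dosages[:, j])
            rb = np.nansum(mb.dosages[:, j])
            t = [[ra, 2 * 500 - ra], [rb, 2 * 400 - rb]]
            res = chi2_two_by_two(t)
            assert scan["chi2"].iloc[j] == pytest.approx(res.statistic, rel=1e-10)
            assert scan["p_raw"].iloc[j] == pytest.approx(res.p_value, rel=1e-8)

    def test_variant_sets_must_match(self):
        ma = make_matrix(np.zeros((5, 2)), variant_ids=["a", "b"])
        mb = make_matrix(np.zeros((5, 2)), variant_ids=["a", "c"], sample_prefix="t")
        with pytest.raises(ValidationError, match="same variants"):
            af_scan(ma, mb)


class TestSummarize:
    def test_all_null_scan(self):
        d = np.random.default_rng(11).integers(0, 3, size=(200, 12)).astype(float)
        scan = af_scan(make_matrix(d), make_matrix(d.copy(), sample_prefix="t"))
        s = summarize_scan(scan)
        assert (s["n_higher_A"], s["n_higher_B"], s["n_nonsignificant"]) == (0, 0, 12)
        assert s["max_abs_diff"] is None

    def test_hand_built_scan_counts(self):
        scan = pd.DataFrame({
            "rsid": ["r1", "r2", "r3"],
            "raf_a": [0.5, 0.3, 0.4], "raf_b": [0.45, 0.33, 0.4],
            "diff": [0.05, -0.03, 0.0], "chi2": [20.0, 15.0, 0.0],
            "p_raw": [1e-6, 1e-4, 1.0], "p_adj": [3e-6, 3e-4, 1.0],
            "direction": ["higher_A", "higher_B", "none"],
            "significant": [True, True, False],
        })
        s = summarize_scan(scan)
        assert (s["n_higher_A"], s["n_higher_B"], s["n_nonsignificant"]) == (1, 1, 1)
        assert s["min_abs_diff"] == pytest.approx(0.03)
        assert s["max_abs_diff"] == pytest.approx(0.05)
        assert len(dumbbell_table(scan)) == 2

    def test_empty_scan_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            summarize_scan(pd.DataFrame())


def test_prevalence_table_shape():
    t = prevalence_table(24_414, 317_889, 2_870, 31_963)
    assert t.sum() == 317_889 + 31_963
    assert chi2_two_by_two(t).p_value < 0.001
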