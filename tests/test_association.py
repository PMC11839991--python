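"""Fisher, CMH, Mantel-Haenszel OR and Firth regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

from rvcollapse.association import (
    StratumTables,
    Table2x2,
    cmh_test,
    firth_logistic,
    fisher_exact_two_sided,
    gene_collapsing_scan,
    mh_odds_ratio_ci,
)
from rvcollapse.simulate import sample_stratum_tables

from oracles import fisher_two_sided_oracle, single_stratum_mh_chi2_oracle


def to_numpy(s: StratumTables):
    return [np.array([[t.a, t.b], [t.c, t.d]]) for _, t in s]


class TestFisher:
    def test_balanced_table_gives_one(self):
        assert fisher_exact_two_sided(Table2x2(1, 1, 1, 1)) == 1.0

    def test_small_table_matches_enumeration(self):
        assert fisher_exact_two_sided(Table2x2(3, 7, 1, 9)) == pytest.approx(
            fisher_two_sided_oracle(3, 7, 1, 9), rel=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_matches_enumeration_oracle_margins_up_to_60(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_two_sided(Table2x2(a, b, c, d)) == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), rel=1e-10
        )

    def test_agrees_with_scipy_on_extreme_counts(self):
        t = Table2x2(267, 14310, 900, 114347)
        _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]])
        assert fisher_exact_two_sided(t) == pytest.approx(p, rel=1e-6)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            Table2x2(-1, 1, 1, 1)

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact_two_sided(Table2x2(0, 10, 0, 20)) == 1.0


class TestCMH:
    def test_single_stratum_equals_closed_form(self):
        s = StratumTables.from_list([("s", Table2x2(10, 90, 5, 95))])
        res = cmh_test(s)
        assert res.statistic == pytest.approx(
            single_stratum_mh_chi2_oracle(10, 90, 5, 95), rel=1e-10
        )
        assert res.p == pytest.approx(stats.chi2.sf(res.statistic, 1), rel=1e-12)

    def test_duplicated_stratum_doubles_deviation_structure(self):
        t = Table2x2(12, 88, 6, 94)
        single = cmh_test(StratumTables.from_list([("a", t)]))
        double = cmh_test(StratumTables.from_list([("a", t), ("b", t)]))
        # sum(a - E) doubles, sum(V) doubles -> statistic doubles
        assert double.statistic == pytest.approx(2 * single.statistic, rel=1e-10)

    @pytest.mark.parametrize(
        "tables",
        [
            [(10, 90, 5, 95)],
            [(10, 90, 5, 95), (7, 143, 12, 238)],
            [(3, 997, 1, 999), (5, 495, 2, 498), (1, 99, 0, 100)],
        ],
    )
    def test_agrees_with_statsmodels(self, tables):
        s = StratumTables.from_list(
            [(str(i), Table2x2(*t)) for i, t in enumerate(tables)]
        )
        res = cmh_test(s)
        sm = StratifiedTable(to_numpy(s)).test_null_odds(correction=False)
        assert res.statistic == pytest.approx(sm.statistic, rel=1e-10)
        assert res.p == pytest.approx(sm.pvalue, rel=1e-10)

    def test_all_degenerate_strata_give_p_one_with_flag(self):
        s = StratumTables.from_list([("a", Table2x2(0, 10, 0, 10))])
        res = cmh_test(s)
        assert res.p == 1.0
        assert "all-degenerate" in res.flags

    def test_null_p_values_are_uniform(self, rng):
        # carrier counts must be large enough for the chi-square(1) reference
        # distribution to hold; at ~400 carriers per table the discreteness
        # of the 2x2 counts no longer shows up in a 2000-sample KS test
        pvals = []
        for _ in range(2000):
            s = sample_stratum_tables(0.05, 1.0, [(5000, 5000), (3000, 3000)], rng)
            pvals.append(cmh_test(s).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_permutation_mode_agrees_with_asymptotic_at_moderate_counts(self, rng):
        s = StratumTables.from_list(
            [("a", Table2x2(30, 970, 18, 982)), ("b", Table2x2(25, 475, 20, 480))]
        )
        asym = cmh_test(s)
        perm = cmh_test(s, method="permutation", n_perm=20000, rng=rng)
        assert perm.p == pytest.approx(asym.p, abs=0.02)


class TestMHOddsRatio:
    def test_single_stratum_reduces_to_cross_product_ratio(self):
        s = StratumTables.from_list([("s", Table2x2(10, 90, 5, 95))])
        assert mh_odds_ratio_ci(s).or_mh == pytest.approx((10 * 95) / (90 * 5), rel=1e-12)

    def test_symmetric_strata_give_unit_odds_ratio(self):
        t = Table2x2(1, 99, 1, 99)
        s = StratumTables.from_list([("a", t), ("b", t)])
        assert mh_odds_ratio_ci(s).or_mh == pytest.approx(1.0, rel=1e-12)

    def test_rbg_interval_matches_statsmodels(self):
        s = StratumTables.from_list(
            [("a", Table2x2(10, 90, 5, 95)), ("b", Table2x2(7, 143, 12, 238))]
        )
        mh = mh_odds_ratio_ci(s)
        stt = StratifiedTable(to_numpy(s))
        assert mh.or_mh == pytest.approx(stt.oddsratio_pooled, rel=1e-10)
        lo, hi = stt.oddsratio_pooled_confint()
        assert mh.ci_low == pytest.approx(lo, rel=1e-9)
        assert mh.ci_high == pytest.approx(hi, rel=1e-9)

    def test_swapping_group_labels_inverts_or_and_keeps_p(self):
        s = StratumTables.from_list(
            [("a", Table2x2(10, 90, 5, 95)), ("b", Table2x2(7, 143, 12, 238))]
        )
        swapped = StratumTables.from_list([(lab, t.swapped()) for lab, t in s])
        assert mh_odds_ratio_ci(swapped).or_mh == pytest.approx(
            1.0 / mh_odds_ratio_ci(s).or_mh, rel=1e-12
        )
        assert cmh_test(swapped).p == pytest.approx(cmh_test(s).p, rel=1e-12)

    def test_identical_margin_strata_collapse_without_changing_or(self):
        t = Table2x2(8, 92, 4, 96)
        split = StratumTables.from_list([("a", t), ("b", t)])
        pooled = StratumTables.from_list(
            [("p", Table2x2(16, 184, 8, 192))]
        )
        assert mh_odds_ratio_ci(split).or_mh == pytest.approx(
            mh_odds_ratio_ci(pooled).or_mh, rel=1e-12
        )

    def test_zero_denominator_flags_infinite_or(self):
        s = StratumTables.from_list([("a", Table2x2(5, 95, 0, 100))])
        mh = mh_odds_ratio_ci(s)
        assert np.isinf(mh.or_mh)
        assert "infinite-or" in mh.flags

    def test_parameter_recovery_covers_truth(self, rng):
        # spiked OR drawn at a large-effect value; CI coverage across seeds
        true_or, f0 = 3.0, 0.005
        covered = 0
        for _ in range(100):
            s = sample_stratum_tables(f0, true_or, [(10000, 10000), (10000, 10000)], rng)
            mh = mh_odds_ratio_ci(s)
            if mh.ci_low <= true_or <= mh.ci_high:
                covered += 1
        assert covered >= 90


class TestFirth:
    def test_complete_separation_returns_finite_estimates(self, rng):
        n = 20
        carrier = np.repeat([0.0, 1.0], n // 2)
        y = carrier.copy()
        X = np.column_stack([np.ones(n), carrier])
        fit = firth_logistic(y, X)
        assert np.all(np.isfinite(fit.params))
        assert fit.converged

    def test_null_p_values_are_uniform(self, rng):
        pvals = []
        for _ in range(200):
            n = 800
            x = rng.standard_normal(n)
            y = rng.binomial(1, 0.3, size=n).astype(float)
            fit = firth_logistic(y, np.column_stack([np.ones(n), x]))
            pvals.append(fit.pvalues[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_estimate_is_nearly_unbiased_at_log_or_one(self, rng):
        betas = []
        for _ in range(100):
            n = 2000
            x = rng.binomial(1, 0.2, size=n).astype(float)
            eta = -1.0 + 1.0 * x
            y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
            fit = firth_logistic(y, np.column_stack([np.ones(n), x]), lrt=False)
            betas.append(fit.params[1])
        assert np.mean(betas) == pytest.approx(1.0, abs=0.05)


class TestGeneScan:
    def test_empty_contrast_group_errors(self, rng):
        import pandas as pd

        pheno = pd.DataFrame(
            {
                "stratum": ["s"] * 10,
                "status": ["case"] * 10,
                "aggressive": [1] * 10,
            },
            index=[f"x{i}" for i in range(10)],
        )
        carr = pd.DataFrame({"G.ptv": [True] * 10}, index=pheno.index)
        with pytest.raises(ValueError):
            gene_collapsing_scan(carr, pheno, "PCa_vs_Ctrl")

    def test_null_type_one_error_is_calibrated(self, rng):
        rejections = 0
        n_tests = 2000
        for _ in range(n_tests):
            s = sample_stratum_tables(0.005, 1.0, [(2000, 2000), (1000, 1000)], rng)
            if cmh_test(s).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_tests <= 0.07

    def test_spiked_gene_reaches_study_wide_significance(self, rng):
        hits = 0
        for _ in range(50):
            s = sample_stratum_tables(0.005, 3.0, [(10000, 10000), (10000, 10000)], rng)
            if cmh_test(s).p < 1e-8:
                hits += 1
        assert hits >= 40
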