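"""Cauchy / Fisher / oracle p-value combiners: examples against the
50-digit oracle, invariances, and tail robustness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scat_twas.combination import (
    CombinedResult,
    ExpressionCorrelation,
    NoCombinableTissuesError,
    TissuePValueSet,
    ZScoreVector,
    _minp_bonferroni,
    combine_table,
    fisher_combine,
    oracle_combine,
    scat_combine,
)

from _oracles import fisher_oracle, scat_oracle


def pset(p, varpi=None, gene="G"):
    p = np.asarray(p, dtype=float)
    tissues = tuple(f"t{i}" for i in range(len(p)))
    return TissuePValueSet(gene, tissues, p, varpi)


class TestScat:
    def test_p_half_gives_zero_statistic(self):
        res = scat_combine(pset([0.5]))
        assert res.statistic == pytest.approx(0.0, abs=1e-15)
        assert res.p == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("q", [0.9, 0.3, 0.05, 1e-4, 1e-12])
    @pytest.mark.parametrize("w", [1.0, 0.2, 7.0])
    def test_single_p_passes_through(self, q, w):
        res = scat_combine(pset([q], varpi=[w]))
        assert res.p == pytest.approx(q, rel=1e-12)

    def test_three_p_example_matches_50_digit_oracle(self):
        res = scat_combine(pset([0.01, 0.1, 0.9]))
        stat, p = scat_oracle(["0.01", "0.1", "0.9"])
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)
        # the combination is decisively non-trivial
        assert res.p == pytest.approx(0.0299214305, abs=1e-9)

    def test_missing_entries_dropped_symmetric_case(self):
        res = scat_combine(pset([0.5, 0.5, np.nan, 0.5]))
        assert res.p == pytest.approx(0.5, abs=1e-12)
        assert res.n_tissues_used == 3

    def test_all_missing_raises(self):
        with pytest.raises(NoCombinableTissuesError, match="no combinable"):
            pset([np.nan, np.nan])

    def test_out_of_range_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            res = scat_combine(pset([0.0, 0.5]))
        assert 0 < res.p < 1

    def test_tiny_p_finite_and_matches_asymptote(self):
        """p containing 1e-300 stays finite; when one tiny p_j dominates, the
        combined p approaches the Cauchy-tail asymptote p_j sum(varpi)/varpi_j
        (T * min p at equal weights)."""
        varpi = np.array([0.2, 0.5, 0.3])
        for tiny in [1e-300, 1e-200, 1e-60, 1e-20]:
            res = scat_combine(pset([tiny, 0.4, 0.6], varpi=varpi))
            assert 0 < res.p < 1e-15
            _, p_oracle = scat_oracle([tiny, 0.4, 0.6], varpi)
            assert res.p == pytest.approx(p_oracle, rel=1e-10)
            assert res.p == pytest.approx(tiny * varpi.sum() / 0.2, rel=1e-3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 13))
    def test_random_configurations_match_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        p = 10 ** rng.uniform(-12, -1e-3, n)
        w = rng.uniform(0.1, 2.0, n)
        res = scat_combine(pset(p, varpi=w))
        _, p_oracle = scat_oracle(p, w)
        assert res.p == pytest.approx(p_oracle, rel=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), c=st.floats(1e-3, 1e3))
    def test_weight_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1 - 1e-6, 5)
        w = rng.uniform(0.1, 1.0, 5)
        assert scat_combine(pset(p, w)).p == pytest.approx(
            scat_combine(pset(p, c * w)).p, rel=1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(1e-8, 1 - 1e-8, 9)
        w = rng.uniform(0.1, 1.0, 9)
        perm = rng.permutation(9)
        assert scat_combine(pset(p, w)).p == pytest.approx(
            scat_combine(pset(p[perm], w[perm])).p, rel=1e-12)

    def test_monotone_in_each_p(self, rng):
        base = rng.uniform(0.05, 0.95, 6)
        p_ref = scat_combine(pset(base)).p
        for j in range(6):
            for new in (base[j] / 2, base[j] / 10, 1e-8):
                mod = base.copy()
                mod[j] = new
                assert scat_combine(pset(mod)).p <= p_ref + 1e-15

    def test_uniform_under_independence(self):
        """Combining 13 independent uniforms, the combined p is exactly
        Uniform(0,1): KS at level 0.01 passes for >= 9 of 10 seeds."""
        passed = 0
        for seed in range(10):
            rng = np.random.default_rng(7000 + seed)
            p = rng.uniform(size=(100_000, 13))
            t = np.tan((0.5 - p) * np.pi).mean(axis=1)
            comb = stats.cauchy.sf(t)
            if stats.kstest(comb, "uniform").pvalue > 0.01:
                passed += 1
        assert passed >= 9


class TestFisher:
    def test_boundary_near_one(self):
        res = fisher_combine(pset([1.0 - 1e-16, 1.0 - 1e-16]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_half_half_matches_chisquare_oracle(self):
        res = fisher_combine(pset([0.5, 0.5]))
        stat, p = fisher_oracle(["0.5", "0.5"])
        assert res.statistic == pytest.approx(2.772588722, abs=1e-8)
        assert res.p == pytest.approx(p, rel=1e-12)
        assert res.p == pytest.approx(0.5965735903, abs=1e-9)

    @pytest.mark.parametrize("q", [0.7, 0.02, 1e-9])
    def test_single_p_passes_through(self, q):
        assert fisher_combine(pset([q])).p == pytest.approx(q, rel=1e-12)

    def test_weights_ignored(self, rng):
        p = rng.uniform(0.01, 0.99, 4)
        assert fisher_combine(pset(p, varpi=[5, 1, 1, 1])).p == pytest.approx(
            fisher_combine(pset(p)).p, rel=1e-14)


class TestOracle:
    def test_null_point(self):
        zs = ZScoreVector("G", ("a", "b", "c"), np.zeros(3))
        c = ExpressionCorrelation(("a", "b", "c"), np.eye(3))
        res = oracle_combine(zs, c)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_chisquare_quantile_at_T1(self):
        zs = ZScoreVector("G", ("a",), np.array([1.959964]))
        c = ExpressionCorrelation(("a",), np.eye(1))
        res = oracle_combine(zs, c)
        assert res.statistic == pytest.approx(3.8414589, abs=1e-6)
        assert res.p == pytest.approx(0.05, abs=1e-6)

    def test_identity_correlation_reduces_to_sum_of_squares(self, rng):
        T = 7
        z = rng.normal(size=T)
        zs = ZScoreVector("G", tuple(f"t{i}" for i in range(T)), z)
        c = ExpressionCorrelation(zs.tissues, np.eye(T))
        res = oracle_combine(zs, c)
        assert res.statistic == pytest.approx(float((z**2).sum()), rel=1e-12)
        assert res.p == pytest.approx(stats.chi2.sf((z**2).sum(), T), rel=1e-12)

    def test_singular_correlation_raises(self):
        zs = ZScoreVector("G", ("a", "b"), np.array([1.0, 1.0]))
        c = ExpressionCorrelation(("a", "b"), np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="not invertible"):
            oracle_combine(zs, c)

    def test_mismatched_tissues_raise(self):
        zs = ZScoreVector("G", ("a", "b"), np.zeros(2))
        c = ExpressionCorrelation(("b", "a"), np.eye(2))
        with pytest.raises(ValueError, match="differ"):
            oracle_combine(zs, c)


class TestMinP:
    def test_bonferroni_calibration(self):
        res = _minp_bonferroni(pset([0.01, 0.5, np.nan]))
        assert res.p == pytest.approx(0.02)
        assert res.n_tissues_used == 2


class TestCombineTable:
    def test_constant_p_across_13_tissues(self):
        df = pd.DataFrame({
            "GENE": ["G1"] * 13,
            "TISSUE": [f"t{i}" for i in range(13)],
            "TWAS_P": [0.5] * 13,
        })
        out = combine_table(df, method="scat")
        assert out.loc[0, "P"] == pytest.approx(0.5, abs=1e-12)

    def test_single_tissue_gene_passes_through(self):
        df = pd.DataFrame({"GENE": ["G1"], "TISSUE": ["t0"], "TWAS_P": [0.037]})
        for method in ("scat", "fisher"):
            out = combine_table(df, method=method)
            assert out.loc[0, "P"] == pytest.approx(0.037, rel=1e-12)

    def test_empty_table_gives_empty_output(self):
        df = pd.DataFrame(columns=["GENE", "TISSUE", "TWAS_P"])
        assert combine_table(df, method="scat").empty

    def test_oracle_without_correlation_raises(self):
        df = pd.DataFrame({"GENE": ["G1"], "TISSUE": ["t0"], "TWAS_Z": [1.0]})
        with pytest.raises(ValueError, match="unknown"):
            combine_table(df, method="oracle")

    def test_grouping_is_input_order_independent(self, rng):
        genes = [f"G{i}" for i in range(4) for _ in range(5)]
        tissues = [f"t{j}" for _ in range(4) for j in range(5)]
        p = rng.uniform(0.001, 0.999, 20)
        df = pd.DataFrame({"GENE": genes, "TISSUE": tissues, "TWAS_P": p})
        shuffled = df.sample(frac=1.0, random_state=11).reset_index(drop=True)
        a = combine_table(df, method="scat").set_index("GENE")["P"]
        b = combine_table(shuffled, method="scat").set_index("GENE")["P"]
        pd.testing.assert_series_equal(a, b, rtol=1e-14)

    def test_weight_override(self):
        df = pd.DataFrame({"GENE": ["G1"] * 2, "TISSUE": ["t0", "t1"],
                           "TWAS_P": [0.01, 0.8]})
        wdf = pd.DataFrame({"GENE": ["G1"] * 2, "TISSUE": ["t0", "t1"],
                            "VARPI": [1.0, 3.0]})
        out = combine_table(df, method="scat", weights=wdf)
        _, expected = scat_oracle([0.01, 0.8], [1.0, 3.0])
        assert out.loc[0, "P"] == pytest.approx(expected, rel=1e-10)
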