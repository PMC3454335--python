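"""Unit and property tests for the statistical primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from exoreg.core import DataError
from exoreg.stats import (
    anova_2x2,
    bh_fdr,
    one_sample_t,
    pearson_r,
    quantile_normalize,
    rank_sum_enumeration_p,
    signed_rank_p,
    two_sample_t,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


class TestQuantileNormalize:
    def test_identical_batches_unchanged(self):
        out = quantile_normalize({"A": [1, 2, 3], "B": [1, 2, 3]})
        np.testing.assert_allclose(out["A"], [1, 2, 3])
        np.testing.assert_allclose(out["B"], [1, 2, 3])

    def test_row_mean_of_sorted(self):
        out = quantile_normalize({"A": [1, 2, 3], "B": [4, 6, 8]})
        np.testing.assert_allclose(out["A"], [2.5, 4.0, 5.5])
        np.testing.assert_allclose(out["B"], [2.5, 4.0, 5.5])

    def test_ties_get_mean_of_tied_quantiles(self):
        out = quantile_normalize({"A": [1, 1, 3], "B": [2, 4, 6]})
        np.testing.assert_allclose(out["A"], [2.0, 2.0, 4.5])
        np.testing.assert_allclose(out["B"], [1.5, 2.5, 4.5])

    def test_empty_batch_rejected(self):
        with pytest.raises(DataError):
            quantile_normalize({"A": [], "B": [1.0]})

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(hst.integers(2, 5), hst.integers(3, 12), hst.integers(0, 2**31 - 1))
    def test_sorted_columns_identical_and_idempotent(self, n_batches, n, seed):
        r = np.random.default_rng(seed)
        batches = {i: r.normal(size=n) for i in range(n_batches)}
        out = quantile_normalize(batches)
        ref = np.sort(out[0])
        for v in out.values():
            np.testing.assert_allclose(np.sort(v), ref, atol=1e-12)
        again = quantile_normalize({k: v for k, v in out.items()})
        for k in out:
            np.testing.assert_allclose(again[k], out[k], atol=1e-12)

    def test_rank_order_preserved(self, rng):
        x = rng.normal(size=20)
        out = quantile_normalize({"A": x, "B": rng.normal(size=20)})
        assert (np.argsort(out["A"]) == np.argsort(x)).all()

    def test_unequal_sizes_supported(self, rng):
        out = quantile_normalize({"A": rng.normal(size=10),
                                  "B": rng.normal(size=7)})
        assert out["A"].size == 10 and out["B"].size == 7


class TestTTests:
    def test_one_sample_df_convention(self, rng):
        assert one_sample_t(rng.normal(size=8), 0.0).df == 7
        assert one_sample_t(rng.normal(size=3), 0.0).df == 2

    def test_one_sample_small_n_closed_form(self):
        res = one_sample_t([1, 2, 3], 0.0)
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        # df=2 Student CDF has the closed form 1/2 + t / (2 sqrt(2 + t^2))
        t = res.statistic
        p_closed = 2 * (0.5 - t / (2 * np.sqrt(2 + t * t)))
        assert res.p_value == pytest.approx(p_closed, abs=1e-10)
        assert res.p_value == pytest.approx(0.0742, abs=1e-4)

    def test_one_sample_zero_variance_flagged(self):
        res = one_sample_t([2.0, 2.0, 2.0], 2.0)
        assert not res.ok and res.p_value is None

    def test_two_sample_pooled_df(self):
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.df == 4
        assert res.statistic == pytest.approx(-3.6742, abs=1e-4)

    def test_two_sample_identical_groups(self):
        res = two_sample_t([1.0, 2.0], [1.0, 2.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_sample_degenerate_constant_groups(self):
        assert two_sample_t([1.0, 1.0], [1.0, 1.0]).p_value == 1.0
        assert not two_sample_t([1.0, 1.0], [2.0, 2.0]).ok


class TestAnova2x2:
    FA = ["a1"] * 4 + ["a2"] * 4
    FB = ["b1", "b1", "b2", "b2"] * 2

    def test_hand_computed_cells(self):
        res = anova_2x2([1, 3, 2, 4, 5, 7, 6, 8], self.FA, self.FB)
        assert res["factor_a"].statistic == pytest.approx(16.0)
        assert res["factor_b"].statistic == pytest.approx(1.0)
        assert res["interaction"].statistic == pytest.approx(0.0)
        assert res["factor_a"].df == 1
        assert res["factor_a"].extra["df_error"] == 4

    def test_symmetric_cells_give_zero_f(self):
        vals = [1, 2, 3] * 4
        fa = ["a1"] * 6 + ["a2"] * 6
        fb = (["b1"] * 3 + ["b2"] * 3) * 2
        res = anova_2x2(vals, fa, fb)
        for r in res.values():
            assert r.statistic == pytest.approx(0.0)

    def test_unbalanced_rejected(self):
        with pytest.raises(DataError):
            anova_2x2([1, 2, 3, 4, 5, 6, 7], ["a1"] * 4 + ["a2"] * 3,
                      ["b1", "b2"] * 3 + ["b1"])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(hst.integers(2, 5), hst.integers(0, 2**31 - 1))
    def test_sums_of_squares_conserved(self, n, seed):
        r = np.random.default_rng(seed)
        y = r.normal(size=4 * n)
        fa = np.repeat(["a1", "a2"], 2 * n)
        fb = np.tile(np.repeat(["b1", "b2"], n), 2)
        res = anova_2x2(y, fa, fb)
        ss_total = ((y - y.mean()) ** 2).sum()
        ss_model = sum(res[k].extra["ss"] for k in
                       ("factor_a", "factor_b", "interaction"))
        ss_err = res["factor_a"].extra["ms_error"] * res["factor_a"].extra["df_error"]
        assert ss_model + ss_err == pytest.approx(ss_total, rel=1e-9)

    def test_agrees_with_statsmodels_ols(self, rng):
        import pandas as pd
        import statsmodels.api as sm_api
        from statsmodels.formula.api import ols

        y = rng.normal(size=12)
        fa = np.repeat(["a1", "a2"], 6)
        fb = np.tile(np.repeat(["b1", "b2"], 3), 2)
        res = anova_2x2(y, fa, fb)
        df = pd.DataFrame({"y": y, "a": fa, "b": fb})
        tab = sm_api.stats.anova_lm(ols("y ~ C(a) * C(b)", df).fit(), typ=2)
        assert res["factor_a"].statistic == pytest.approx(tab["F"]["C(a)"])
        assert res["factor_b"].statistic == pytest.approx(tab["F"]["C(b)"])
        assert res["interaction"].statistic == pytest.approx(
            tab["F"]["C(a):C(b)"])


class TestSignedRank:
    def test_printed_dialect_pairs(self):
        assert round(signed_rank_p(10, 5), 4) == 0.5896
        assert round(signed_rank_p(10, 4), 4) == 0.1003

    def test_from_differences(self):
        res = wilcoxon_signed_rank([1, -2, 3, -4, 5])
        assert res.statistic == 9.0
        assert res.n_effective == 5
        assert res.p_value == pytest.approx(0.7874, abs=1e-4)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, -2.0])
        assert res.n_effective == 2

    def test_all_zero_flagged(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert not res.ok

    def test_matches_scipy_dialect(self, rng):
        # same approximation as scipy's correction=True 'approx' mode
        for _ in range(10):
            d = rng.normal(size=12)
            ours = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, correction=True, method="approx")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_mode_matches_scipy_exact(self, rng):
        for _ in range(5):
            d = rng.normal(size=8)
            ours = wilcoxon_signed_rank(d, method="exact")
            ref = sps.wilcoxon(d, method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestRankSum:
    def test_small_exact_enumeration_value(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4, 5])
        assert res.p_value == pytest.approx(0.2)
        assert "exact" in res.method

    def test_complete_tie(self):
        assert wilcoxon_rank_sum([1.0], [1.0]).p_value == 1.0

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(hst.integers(2, 4), hst.integers(2, 4), hst.integers(0, 2**31 - 1))
    def test_exact_equals_enumeration_oracle(self, n1, n2, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=n1), r.normal(size=n2)
        res = wilcoxon_rank_sum(x, y)
        assert res.p_value == pytest.approx(rank_sum_enumeration_p(x, y),
                                            rel=1e-9)

    def test_exact_vs_approx_close_n6(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=6), rng.normal(size=6)
            exact = wilcoxon_rank_sum(x, y, exact_limit=12)
            approx = wilcoxon_rank_sum(x, y, exact_limit=0)
            assert abs(exact.p_value - approx.p_value) < 0.02


class TestBhFdr:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_single_and_tied(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])
        np.testing.assert_allclose(bh_fdr([0.05, 0.05]), [0.05, 0.05])

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=20))
    def test_matches_brute_force_definition(self, ps):
        ps = np.asarray(ps)
        q = bh_fdr(ps)
        m = ps.size
        order = np.argsort(ps, kind="stable")
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            cands = [ps[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
            expected[idx] = min(1.0, min(cands))
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestPearson:
    def test_perfect_correlations(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]).statistic == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [-1, -2, -3]).statistic == pytest.approx(-1.0)

    def test_covariance_formula_value(self):
        assert pearson_r([1, 2, 3], [1, 2, 4]).statistic == pytest.approx(
            0.9820, abs=1e-4)

    def test_zero_variance_flagged(self):
        assert not pearson_r([1, 1, 1], [1, 2, 3]).ok
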