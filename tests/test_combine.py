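"""Combined p-values: worked examples, oracles, and distributional properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from repsum.combine import (
    CombinedResult,
    StudyPair,
    WeightScheme,
    budget,
    combine,
    combined_pvalues,
    fisher_critical_product,
    irwin_hall_cdf,
    p_edgington,
    p_edgington_weighted,
    p_fisher,
    p_meta,
    p_two_trials,
)

probs = st.floats(1e-6, 1.0 - 1e-6)
weights_st = st.floats(0.05, 20.0)


class TestIrwinHall:
    @pytest.mark.parametrize(
        "x, n, expected",
        [
            (1.0, 2, 0.5),  # symmetry of U1+U2 about 1
            (0.048, 2, 0.048**2 / 2),  # small-sum branch E^2/2
            (0.1554, 3, 0.1554**3 / 6),  # small-sum branch E^3/6
            (-0.5, 2, 0.0),
            (2.0, 2, 1.0),
            (3.5, 3, 1.0),
        ],
    )
    def test_closed_form_values(self, x, n, expected):
        assert irwin_hall_cdf(x, n) == pytest.approx(expected, rel=1e-12, abs=1e-15)

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 10])
    def test_matches_scipy_reference(self, n):
        """Independent oracle: scipy's Irwin-Hall distribution."""
        x = np.linspace(-0.5, n + 0.5, 47)
        expected = stats.irwinhall(n).cdf(x)
        np.testing.assert_allclose(irwin_hall_cdf(x, n), expected, atol=1e-12)
        # scalar path agrees with the array path
        for xi in x[::5]:
            assert irwin_hall_cdf(float(xi), n) == pytest.approx(
                float(stats.irwinhall(n).cdf(xi)), abs=1e-12
            )

    @pytest.mark.parametrize("bad_n", [0, -1, 1.5, 11, True])
    def test_rejects_invalid_n(self, bad_n):
        with pytest.raises(ValueError):
            irwin_hall_cdf(0.5, bad_n)


class TestWorkedExamples:
    """The printed study-pair examples where the criteria disagree."""

    def test_edgington_succeeds_where_two_trials_fails(self):
        pair = StudyPair(0.026, 0.001)
        pe = p_edgington(pair)
        p2 = p_two_trials(pair)
        assert pe.p_combined == pytest.approx(0.027**2 / 2, rel=1e-12)  # 0.0004
        assert p2.p_combined == pytest.approx(6.76e-4, rel=1e-12)
        assert pe.success and not p2.success

    def test_two_trials_succeeds_where_edgington_fails(self):
        pair = StudyPair(0.024, 0.024)
        pe = p_edgington(pair)
        p2 = p_two_trials(pair)
        assert pe.p_combined == pytest.approx(1.152e-3, rel=1e-12)  # 0.001
        assert p2.p_combined == pytest.approx(5.76e-4, rel=1e-12)
        assert p2.success and not pe.success

    def test_median_pair_gives_median_p(self):
        assert p_edgington(StudyPair(0.5, 0.5)).p_combined == pytest.approx(0.5)

    def test_weighted_boundary_attains_overall_level(self):
        # p_o + 2*p_r = 0.05 exactly exhausts the weighted budget at alpha=0.025
        res = p_edgington_weighted(StudyPair(0.035, 0.0075), WeightScheme(1, 2))
        assert res.p_combined == pytest.approx(0.05**2 / 4, rel=1e-12)
        assert res.success  # equality counts as success

    def test_weighted_middle_branch(self):
        res = p_edgington_weighted(StudyPair(0.4, 0.4), WeightScheme(1, 2))
        assert res.p_combined == pytest.approx(1.2 / 2 - 0.25, rel=1e-12)

    def test_fisher_closed_form(self):
        x = -2 * math.log(0.026 * 0.001)
        expected = math.exp(-x / 2) * (1 + x / 2)  # chi2_4 survival
        assert p_fisher(StudyPair(0.026, 0.001)).p_combined == pytest.approx(expected, rel=1e-10)

    def test_fisher_degenerate_pair(self):
        assert p_fisher(StudyPair(1.0, 1.0)).p_combined == pytest.approx(1.0, abs=1e-12)

    def test_meta_null_pair(self):
        assert p_meta(StudyPair(0.5, 0.5, c=1)).p_combined == pytest.approx(0.5, abs=1e-12)

    def test_meta_equal_borderline_pair(self):
        z = stats.norm.isf(0.025)
        expected = stats.norm.sf(2 * z / math.sqrt(2))
        res = p_meta(StudyPair(0.025, 0.025, c=1))
        assert res.p_combined == pytest.approx(expected, rel=1e-10)
        assert res.p_combined == pytest.approx(2.79e-3, rel=2e-3)

    def test_meta_limit_all_weight_on_original(self):
        res = p_meta(StudyPair(0.01, 0.9, c=1e-12))
        assert res.p_combined == pytest.approx(0.01, rel=1e-4)

    def test_meta_requires_variance_ratio(self):
        with pytest.raises(ValueError, match="meta"):
            p_meta(StudyPair(0.01, 0.01))


class TestBudget:
    def test_unweighted_budget(self):
        assert budget(0.025) == pytest.approx(math.sqrt(2) * 0.025, rel=1e-14)

    def test_one_two_weighting_doubles_alpha(self):
        assert budget(0.025, WeightScheme(1, 2)) == pytest.approx(0.05, rel=1e-14)

    def test_budget_scales_with_weights_but_not_decisions(self):
        # (2,4) budget is 0.1 on the statistic 2*p_o + 4*p_r: same decisions as (1,2)
        assert budget(0.025, WeightScheme(2, 4)) == pytest.approx(0.1, rel=1e-14)
        pair = StudyPair(0.012, 0.017)
        a = p_edgington_weighted(pair, WeightScheme(1, 2))
        b = p_edgington_weighted(pair, WeightScheme(2, 4))
        assert a.p_combined == pytest.approx(b.p_combined, rel=1e-12)

    def test_budget_outside_first_branch_rejected(self):
        with pytest.raises(ValueError, match="branch"):
            budget(0.4, WeightScheme(1, 50))

    def test_fisher_critical_product(self):
        cf = fisher_critical_product(0.025)
        assert cf == pytest.approx(6e-5, rel=0.05)
        # success iff the product of p-values is at most c_F
        eps = 1e-9
        assert p_fisher(StudyPair(0.01, (cf - eps) / 0.01)).success
        assert not p_fisher(StudyPair(0.01, (cf + eps) / 0.01)).success

    @given(
        alpha=st.floats(0.001, 0.1),
        po=probs,
        pr=probs,
    )
    @settings(max_examples=200, deadline=None)
    def test_threshold_equivalence(self, alpha, po, pr):
        """Success at alpha^2 is the same event as the sum within budget."""
        b = budget(alpha)
        res = p_edgington(StudyPair(po, pr), alpha=alpha)
        assert res.success == (po + pr <= b + 1e-15)

    @given(alpha=st.floats(0.001, 0.05), po=probs, pr=probs, wr=st.floats(0.5, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_threshold_equivalence_weighted(self, alpha, po, pr, wr):
        w = WeightScheme(1.0, wr)
        b = budget(alpha, w)
        res = p_edgington_weighted(StudyPair(po, pr), w, alpha=alpha)
        assert res.success == (po + wr * pr <= b * (1 + 1e-13))


class TestWeightedCdfProperties:
    @pytest.mark.parametrize("w", [(1, 1), (1, 2), (0.3, 1.7), (2, 5), (4, 1.5)])
    def test_continuity_at_branch_points(self, w):
        wo, wr = min(w), max(w)
        from repsum.combine import _weighted_sum_cdf

        eps = 1e-13
        for point in (wo, wr):
            left = _weighted_sum_cdf(point - eps, *w)
            right = _weighted_sum_cdf(point + eps, *w)
            assert abs(left - right) < 1e-12
        assert _weighted_sum_cdf(wo + wr, *w) == pytest.approx(1.0, abs=1e-12)

    @given(po=probs, pr=probs, k=st.floats(0.01, 100.0), wo=weights_st, wr=weights_st)
    @settings(max_examples=200, deadline=None)
    def test_weight_scale_invariance(self, po, pr, k, wo, wr):
        pair = StudyPair(po, pr)
        a = p_edgington_weighted(pair, WeightScheme(wo, wr)).p_combined
        b = p_edgington_weighted(pair, WeightScheme(k * wo, k * wr)).p_combined
        assert a == pytest.approx(b, rel=1e-10, abs=1e-14)

    @given(po=probs, pr=probs, w=weights_st)
    @settings(max_examples=200, deadline=None)
    def test_equal_weights_reduce_to_unweighted(self, po, pr, w):
        pair = StudyPair(po, pr)
        a = p_edgington_weighted(pair, WeightScheme(w, w)).p_combined
        b = p_edgington(pair).p_combined
        assert a == pytest.approx(b, rel=1e-10, abs=1e-14)

    @given(po=probs, pr=probs)
    @settings(max_examples=100, deadline=None)
    def test_symmetry_of_unweighted_sum(self, po, pr):
        assert p_edgington(StudyPair(po, pr)).p_combined == pytest.approx(
            p_edgington(StudyPair(pr, po)).p_combined, rel=1e-12
        )

    def test_weighted_cdf_against_monte_carlo(self, rng):
        """Oracle: empirical Pr(w_o*U1 + w_r*U2 <= E) on random configurations."""
        n = 200_000
        u1, u2 = rng.uniform(size=n), rng.uniform(size=n)
        for _ in range(20):
            wo, wr = rng.uniform(0.1, 5.0, size=2)
            e = rng.uniform(0.0, wo + wr)
            mc = np.mean(wo * u1 + wr * u2 <= e)
            se = max(math.sqrt(mc * (1 - mc) / n), 1e-6)
            from repsum.combine import _weighted_sum_cdf

            assert abs(_weighted_sum_cdf(e, wo, wr) - mc) < 3 * se


@pytest.mark.parametrize("method", ["edgington", "edgington_weighted", "two_trials", "fisher", "meta"])
class TestPerMethodProperties:
    def test_null_uniformity(self, method, rng):
        """Validity: under the intersection null every combined p is Uniform(0,1)."""
        n = 100_000
        po, pr = rng.uniform(size=n), rng.uniform(size=n)
        p = combined_pvalues(po, pr, method, c=1.0)
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_monotone_in_each_argument(self, method, rng):
        grid = np.sort(rng.uniform(1e-4, 1 - 1e-4, size=40))
        for fixed in rng.uniform(0.01, 0.99, size=5):
            along_po = combined_pvalues(grid, np.full_like(grid, fixed), method, c=1.0)
            along_pr = combined_pvalues(np.full_like(grid, fixed), grid, method, c=1.0)
            assert np.all(np.diff(along_po) >= -1e-12)
            assert np.all(np.diff(along_pr) >= -1e-12)

    def test_scalar_and_batch_paths_agree(self, method, rng):
        po, pr = rng.uniform(0.001, 0.999, size=10), rng.uniform(0.001, 0.999, size=10)
        batch = combined_pvalues(po, pr, method, c=2.0)
        for i in range(10):
            res = combine(StudyPair(po[i], pr[i], c=2.0), method)
            assert isinstance(res, CombinedResult)
            assert res.p_combined == pytest.approx(float(batch[i]), rel=1e-12)


class TestValidation:
    @pytest.mark.parametrize("bad", [-0.1, 1.5, float("nan")])
    def test_rejects_out_of_range_pvalues(self, bad):
        with pytest.raises(ValueError):
            StudyPair(bad, 0.5)

    def test_clips_exact_zero_and_one(self, caplog):
        pair = StudyPair(0.0, 1.0)
        assert 0.0 < pair.p_o < pair.p_r < 1.0

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError):
            WeightScheme(0.0, 1.0)

    def test_rejects_nonpositive_variance_ratio(self):
        with pytest.raises(ValueError):
            StudyPair(0.5, 0.5, c=-1.0)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            combine(StudyPair(0.1, 0.1), "stouffer")
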