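"""Contingency tests against enumeration oracles; tetrad-viability model."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from sporemap.xo_stats import (
    ContingencyError,
    NDModelParams,
    TetradCounts,
    chisq,
    chisq_mc,
    compare_maps,
    exact_rxc,
    fisher_exact,
    nd_fit,
    nd_model_probs,
    nd_zero_attribution,
    spore_viability,
    tetrad_distribution_test,
    total_viability,
)


# -- independent oracles -------------------------------------------------

def fisher_2x2_oracle(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())

def exact_2xc_oracle(table):
    """Probability-ordering exact p for a 2 x c table by brute-force
    composition enumeration (factorials, no log-space tricks)."""
    table = np.asarray(table)
    col = table.sum(axis=0)
    r1 = int(table[0].sum())
    n = int(table.sum())
    denom = math.comb(n, r1)

    def prob(first_row):
        num = 1
        for a, cj in zip(first_row, col):
            num *= math.comb(int(cj), int(a))
        return num / denom

    p_obs = prob(table[0])
    total = 0.0
    ranges = [range(int(c) + 1) for c in col]
    for combo in itertools.product(*ranges):
        if sum(combo) != r1:
            continue
        p = prob(combo)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


class TestFisherExact:
    def test_identical_rows_give_unity(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_published_double_crossover_table_significant(self):
        # 16 of 100 vs 1 of 100 multi-crossover spores
        assert fisher_exact([[16, 84], [1, 99]]) < 0.01

    @pytest.mark.parametrize("table", [
        [[2, 8], [8, 2]], [[1, 9], [5, 5]], [[0, 10], [4, 6]],
        [[3, 0], [0, 3]], [[7, 2], [3, 8]], [[12, 3], [5, 11]],
    ])
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact(table) == pytest.approx(
            fisher_2x2_oracle(table), abs=1e-10)

    def test_large_table_routes_to_exact_rxc(self):
        t = [[4, 1, 0], [1, 3, 4]]
        assert fisher_exact(t) == pytest.approx(exact_2xc_oracle(t),
                                                abs=1e-10)


class TestExactRxc:
    @pytest.mark.parametrize("table", [
        [[5, 3, 2], [1, 4, 5]],
        [[2, 0, 1, 3], [0, 4, 2, 1]],
        [[6, 2, 1, 0, 1], [1, 3, 2, 2, 2]],
        [[1, 1, 1, 1, 1], [1, 1, 1, 1, 1]],
    ])
    def test_matches_brute_force_composition_oracle(self, table):
        assert exact_rxc(table) == pytest.approx(exact_2xc_oracle(table),
                                                 abs=1e-10)

    def test_three_rows_rejected(self):
        with pytest.raises(ContingencyError, match="2 x c"):
            exact_rxc([[1, 2], [2, 1], [1, 1]])

    def test_enumeration_cap(self):
        big = [[500] * 5, [500] * 5]
        with pytest.raises(ContingencyError, match="cap"):
            exact_rxc(big, max_tables=1000)


class TestChisq:
    def test_proportional_rows_give_zero_statistic(self):
        x2, df, p = chisq([[10, 20, 30], [20, 40, 60]])
        assert x2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        x2, df, p = chisq([[10, 90], [30, 70]])
        assert x2 == pytest.approx(12.5)
        assert df == 1

    def test_two_by_five_df(self):
        _, df, _ = chisq([[78, 13, 7, 1, 1], [62, 11, 12, 4, 17]])
        assert df == 4

    def test_zero_margin_is_error(self):
        with pytest.raises(ContingencyError, match="margin"):
            chisq([[0, 0], [5, 5]])

    def test_matches_scipy_no_correction(self):
        table = [[12, 5, 9], [3, 14, 6]]
        x2, df, p = chisq(table)
        ref = sps.chi2_contingency(np.asarray(table), correction=False)
        assert x2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestChisqMC:
    def test_proportional_rows_near_unity(self):
        _, p = chisq_mc([[10, 20], [20, 40]], B=2000, seed=0)
        assert p >= 0.99

    def test_same_seed_same_p(self):
        t = [[10, 90], [30, 70]]
        assert chisq_mc(t, B=2000, seed=5) == chisq_mc(t, B=2000, seed=5)

    def test_add_one_estimator_never_zero(self):
        _, p = chisq_mc([[50, 0], [0, 50]], B=2000, seed=1)
        assert p >= 1 / 2001

    def test_b_below_one_is_error(self):
        with pytest.raises(ContingencyError, match="B"):
            chisq_mc([[1, 2], [2, 1]], B=0)

    def test_converges_with_b(self):
        """Estimates at B = 2000 and B = 50000 agree within Monte-Carlo
        error, and both approximate the asymptotic p for a comfortable
        table."""
        t = [[30, 70], [45, 55]]
        _, p_small = chisq_mc(t, B=2000, seed=3)
        _, p_big = chisq_mc(t, B=50_000, seed=4)
        se = np.sqrt(p_big * (1 - p_big) / 2000)
        assert abs(p_small - p_big) <= 4 * se


class TestTetradViability:
    def test_all_four_viable(self):
        assert total_viability(TetradCounts.from_dict({4: 100})) == 100.0

    def test_all_dead(self):
        assert total_viability(TetradCounts.from_dict({0: 100})) == 0.0

    def test_weighted_sum_on_published_wildtype_counts(self):
        tc = TetradCounts.from_dict({4: 78, 3: 13, 2: 7, 1: 0, 0: 1})
        # 365 viable spores of 4 x 99 = 92.17%, printed as 92.2
        assert total_viability(tc) == pytest.approx(100 * 365 / 396)
        assert round(total_viability(tc), 1) == 92.2

    def test_published_mutant_counts(self):
        tc = TetradCounts.from_dict({4: 62, 3: 11, 2: 12, 1: 4, 0: 17})
        assert round(total_viability(tc), 1) == 72.9

    def test_zero_tetrads_is_error(self):
        with pytest.raises(ContingencyError):
            total_viability(TetradCounts.from_dict({}))

    def test_identical_distributions_p_one(self):
        tc = TetradCounts.from_dict({4: 10, 3: 5, 2: 3, 1: 1, 0: 1})
        assert tetrad_distribution_test(tc, tc) == pytest.approx(1.0)

    def test_extreme_distributions_p_tiny(self):
        a = TetradCounts.from_dict({4: 100})
        b = TetradCounts.from_dict({0: 100})
        assert tetrad_distribution_test(a, b) < 1e-15

    def test_small_tables_match_enumeration(self):
        a = TetradCounts.from_dict({4: 8, 3: 2, 2: 1, 1: 0, 0: 1})
        b = TetradCounts.from_dict({4: 4, 3: 1, 2: 3, 1: 2, 0: 5})
        table = np.array([a.counts, b.counts])
        keep = table.sum(axis=0) > 0
        assert tetrad_distribution_test(a, b) == pytest.approx(
            exact_2xc_oracle(table[:, keep]), abs=1e-10)

    def test_published_distributions_differ(self):
        wt = TetradCounts.from_dict({4: 78, 3: 13, 2: 7, 1: 0, 0: 1})
        mut = TetradCounts.from_dict({4: 62, 3: 11, 2: 12, 1: 4, 0: 17})
        assert tetrad_distribution_test(wt, mut) < 0.01


class TestNDModel:
    def test_no_failure_modes(self):
        p = nd_model_probs(NDModelParams(v=0, d=0, m=0))
        assert p == pytest.approx([1, 0, 0, 0, 0])

    def test_certain_mi_nd(self):
        p = nd_model_probs(NDModelParams(v=0, d=1, m=0))
        assert p == pytest.approx([0, 0, 0, 0, 1])

    def test_certain_single_division_geometry(self):
        # m = 1: both daughters always fail, so zero viable
        p = nd_model_probs(NDModelParams(v=0, d=0, m=1))
        assert p == pytest.approx([0, 0, 0, 0, 1])

    @pytest.mark.parametrize("v,d,m", [
        (0.0, 0.0, 0.0), (0.3, 0.1, 0.2), (0.9, 0.5, 0.5),
        (0.02, 0.1, 0.05), (1.0, 0.0, 0.0),
    ])
    def test_probabilities_sum_to_one(self, v, d, m):
        assert nd_model_probs(NDModelParams(v, d, m)).sum() == \
            pytest.approx(1.0)

    def test_pure_death_is_binomial(self):
        v = 0.25
        p = nd_model_probs(NDModelParams(v=v, d=0, m=0))
        expect = [sps.binom.pmf(k, 4, 1 - v) for k in (4, 3, 2, 1, 0)]
        assert p == pytest.approx(expect)


class TestNDFit:
    def test_perfect_tetrads_fit_boundary(self):
        fit = nd_fit(TetradCounts.from_dict({4: 100}), n_boot=0)
        assert fit.v == pytest.approx(0.0, abs=1e-6)
        assert fit.d == pytest.approx(0.0, abs=1e-6)
        assert fit.m == pytest.approx(0.0, abs=1e-6)

    def test_mle_beats_truth(self):
        truth = NDModelParams(v=0.05, d=0.1, m=0.05)
        rng = np.random.default_rng(3)
        counts = rng.multinomial(2000, nd_model_probs(truth))
        tc = TetradCounts(tuple(counts))
        fit = nd_fit(tc, n_boot=0)
        ll_truth = float((counts * np.log(nd_model_probs(truth))).sum())
        assert fit.loglik >= ll_truth - 1e-6

    def test_too_few_tetrads_rejected(self):
        with pytest.raises(ContingencyError, match="at least"):
            nd_fit(TetradCounts.from_dict({4: 5}))

    def test_bootstrap_ci_brackets_estimate(self):
        truth = NDModelParams(v=0.04, d=0.12, m=0.06)
        rng = np.random.default_rng(4)
        counts = rng.multinomial(3000, nd_model_probs(truth))
        fit = nd_fit(TetradCounts(tuple(counts)), n_boot=200, seed=8)
        for name, est in zip("vdm", (fit.v, fit.d, fit.m)):
            lo, hi = fit.ci[name]
            assert lo - 1e-9 <= est <= hi + 1e-9


class TestZeroAttribution:
    def test_closed_form(self):
        r = nd_zero_attribution(NDModelParams(v=0, d=0.01, m=0.01))
        assert r == pytest.approx(0.01 / (0.99 * 0.0001))

    def test_no_mi_gives_zero(self):
        assert nd_zero_attribution(NDModelParams(v=0, d=0, m=0.1)) == 0.0

    def test_no_mii_gives_infinity(self):
        assert nd_zero_attribution(NDModelParams(v=0, d=0.1, m=0)) == \
            float("inf")


class TestSporeViability:
    def test_uniform_spots(self):
        assert spore_viability([(50, 50)] * 5) == 100.0
        assert spore_viability([(25, 50)] * 5) == 50.0

    def test_unweighted_not_pooled(self):
        # unweighted mean of 10% and 60% is 35%; pooling would give 26.7%
        assert spore_viability([(10, 100), (30, 50)]) == pytest.approx(35.0)

    def test_empty_is_error(self):
        with pytest.raises(ContingencyError):
            spore_viability([])


class TestCompareMaps:
    def _map(self, recs, infs=None, kb=None):
        from sporemap.xo_map import Interval, IntervalMap
        infs = infs or [100] * len(recs)
        kb = kb or [50.0] * len(recs)
        ivs = tuple(
            Interval(name=f"i{k}", left_marker=f"m{k}",
                     right_marker=f"m{k+1}", n_informative=n,
                     n_recombinant=r, physical_kb=K)
            for k, (r, n, K) in enumerate(zip(recs, infs, kb)))
        return IntervalMap(chrom_id="c", intervals=ivs)

    def test_identical_maps_all_unity(self):
        im = self._map([5, 10, 3])
        cmp = compare_maps(im, im, B=500, seed=0)
        assert all(p == pytest.approx(1.0)
                   for p in cmp.per_interval_p.values())
        assert cmp.whole_chromosome_p == pytest.approx(1.0)
        assert cmp.total_cM_a == cmp.total_cM_b

    def test_tripled_interval_flagged(self):
        im_a = self._map([4, 10, 3])
        im_b = self._map([4, 30, 3])
        cmp = compare_maps(im_a, im_b, B=2000, seed=1)
        assert cmp.per_interval_p["i1"] < 0.05

    def test_interval_mismatch_is_error(self):
        with pytest.raises(ContingencyError, match="different"):
            compare_maps(self._map([1, 2]), self._map([1, 2, 3]))
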