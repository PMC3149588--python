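"""Hypergeometric ORA, WMW test, BH correction, and the result filters."""

import itertools
import math

import numpy as np
import pytest

from agenrich import (
    FilterConfig,
    GeneSet,
    OraResult,
    apply_filters,
    bh_adjust,
    hypergeom_tail,
    ora_test,
    wmw_test,
)
from agenrich.gene_universe import AnnotationCatalog
from agenrich.stats_core import ora_analysis


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct summation of counting ratios."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    ) / total


def wmw_oracle(test_values, ref_values):
    """Exact permutation p by enumerating group assignments and counting
    (test, ref) pairs directly — independent of the rank-based route."""
    def u_of(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    pooled = list(test_values) + list(ref_values)
    n1 = len(test_values)
    u_obs = u_of(test_values, ref_values)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if u_of(chosen, rest) >= u_obs - 1e-9:
            hits += 1
        total += 1
    return u_obs, hits / total


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "k,N,K,n,expected",
        [
            (4, 10, 5, 4, 5 / 210),   # all draws annotated
            (3, 6, 3, 3, 1 / 20),
            (0, 50, 10, 5, 1.0),      # P(X >= 0) is always 1
            (2, 10, 2, 2, 1 / 45),
        ],
    )
    def test_known_values(self, k, N, K, n, expected):
        assert hypergeom_tail(k, N, K, n) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_oracle_small_populations(self):
        for N in range(1, 10):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeom_tail(k, N, K, n) == pytest.approx(
                            hypergeom_tail_oracle(k, N, K, n), rel=1e-10
                        )

    def test_non_increasing_in_k(self):
        for N, K, n in [(20, 7, 9), (50, 25, 10), (12, 12, 5)]:
            values = [hypergeom_tail(k, N, K, n) for k in range(min(n, K) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize(
        "k,N,K,n", [(1, 10, 11, 5), (1, 10, 5, 11), (6, 10, 5, 7), (-1, 10, 5, 5)]
    )
    def test_domain_violations_rejected(self, k, N, K, n):
        with pytest.raises(ValueError):
            hypergeom_tail(k, N, K, n)


class TestOraTest:
    def test_fully_annotated_test_set(self):
        test = GeneSet("t", {"g1", "g2"})
        ref = GeneSet("r", {f"g{i}" for i in range(3, 11)})
        namespace = test.members | ref.members
        r = ora_test(test, ref, {"g1", "g2"}, namespace)
        assert (r.N, r.K, r.n, r.k) == (10, 2, 2, 2)
        assert r.p_raw == pytest.approx(1 / 45, rel=1e-12)

    def test_disjoint_category_gives_p_one(self):
        test = GeneSet("t", {"g1"})
        ref = GeneSet("r", {"g2", "g3"})
        r = ora_test(test, ref, {"g9"}, test.members | ref.members | {"g9"})
        assert r.k == 0 and r.p_raw == 1.0

    def test_genes_outside_namespace_dropped_from_n(self):
        test = GeneSet("t", {"g1", "g2", "gx"})
        ref = GeneSet("r", {"g3", "g4"})
        namespace = {"g1", "g2", "g3", "g4"}
        r = ora_test(test, ref, {"g1"}, namespace)
        assert r.n == 2 and r.N == 4

    def test_overlapping_test_and_reference_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ora_test(GeneSet("t", {"g1"}), GeneSet("r", {"g1", "g2"}),
                     set(), {"g1", "g2"})

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            ora_test(GeneSet("t", {"g1"}), GeneSet("r", {"g2"}), set(), {"g9"})


class TestWmw:
    @pytest.mark.parametrize(
        "test_vals,ref_vals,u,p",
        [
            ([3, 4, 5], [1, 2], 6.0, 0.1),
            ([2], [1], 1.0, 0.5),
            ([1, 1], [1, 1], 2.0, 1.0),  # all tied, half weight each pair
        ],
    )
    def test_known_small_samples(self, test_vals, ref_vals, u, p):
        r = wmw_test(test_vals, ref_vals)
        assert r.u_statistic == pytest.approx(u)
        assert r.p_raw == pytest.approx(p)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wmw_test([], [1.0])

    def test_all_identical_values_degenerate(self, caplog):
        with caplog.at_level("WARNING", logger="agenrich"):
            r = wmw_test([2.0, 2.0, 2.0] * 5, [2.0] * 10)
        assert r.p_raw == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_branch_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 10 - n1 + 1))
        # tied-heavy values from a 4-letter alphabet
        x = rng.integers(0, 4, size=n1).astype(float).tolist()
        y = rng.integers(0, 4, size=n2).astype(float).tolist()
        u_oracle, p_oracle = wmw_oracle(x, y)
        r = wmw_test(x, y)
        assert r.u_statistic == pytest.approx(u_oracle)
        assert r.p_raw == pytest.approx(p_oracle, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_normal_approximation_close_to_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        n1 = int(rng.integers(3, 7))
        n2 = int(rng.integers(5, 13 - n1))
        x = rng.normal(0.5, 1, size=n1).tolist()
        y = rng.normal(0, 1, size=n2).tolist()
        exact = wmw_test(x, y).p_raw
        approx = wmw_test(x, y, exact_limit=0).p_raw
        assert abs(approx - exact) <= 0.01

    def test_approximate_branch_agrees_with_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        x = rng.normal(0.3, 1, size=40)
        y = np.round(rng.normal(0, 1, size=120), 1)  # induce ties
        r = wmw_test(x.tolist(), y.tolist())
        u_sp, p_sp = mannwhitneyu(
            x, y, alternative="greater", method="asymptotic"
        )
        assert r.u_statistic == pytest.approx(float(u_sp))
        assert r.p_raw == pytest.approx(float(p_sp), rel=1e-9)


def bh_rejections_oracle(p, alpha):
    """Independent BH step-up: reject the i* smallest p with
    p_(i) <= alpha*i/m for the largest such i."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    i_star = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= alpha * rank / m:
            i_star = rank
    return {order[i] for i in range(i_star)}


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.05], [0.05]),
            ([0.04, 0.01], [0.04, 0.02]),
        ],
    )
    def test_known_values(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(20))
    def test_elementwise_bounds_and_rejection_set(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 40))
        p = rng.random(m).tolist()
        adj = bh_adjust(p)
        assert all(a >= pi - 1e-15 for a, pi in zip(adj, p))
        assert all(a <= 1.0 for a in adj)
        for alpha in (0.01, 0.05, 0.2):
            ours = {i for i, a in enumerate(adj) if a < alpha}
            # adjusted-p rejection {adj < alpha} vs step-up with strict <
            oracle = bh_rejections_oracle(p, alpha)
            strict_oracle = {
                i for i in oracle
                if bh_adjust(p)[i] < alpha
            }
            assert ours <= oracle
            assert ours == strict_oracle

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.random(200)
        _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p.tolist()) == pytest.approx(adj_sm.tolist())


class TestFilters:
    def make_result(self, **kw):
        base = dict(set_name="s", namespace="ns", category_id="c",
                    N=100, K=10, n=40, k=2, p_raw=0.001, p_adjusted=0.01)
        base.update(kw)
        return OraResult(**base)

    def test_prevalence_boundary_inclusive(self):
        r = self.make_result(k=2)
        apply_filters([r], FilterConfig(), prevalence_denominator=40)
        assert r.prevalence == pytest.approx(0.05)
        assert r.passes_filters

    def test_below_prevalence_fails(self):
        r = self.make_result(k=1)
        apply_filters([r], FilterConfig(), prevalence_denominator=40)
        assert not r.passes_filters

    def test_alpha_boundary_is_strict(self):
        r = self.make_result(p_adjusted=0.05, k=5)
        apply_filters([r], FilterConfig(), prevalence_denominator=40)
        assert not r.passes_filters

    def test_min_category_size_on_population_K(self):
        r = self.make_result(K=1, k=1, p_adjusted=0.001)
        apply_filters([r], FilterConfig(), prevalence_denominator=10)
        assert not r.passes_filters

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(alpha=1.5)
        with pytest.raises(ValueError):
            FilterConfig(min_category_size=0)


class TestOraAnalysis:
    def test_family_adjustment_and_population_restriction(self):
        test = GeneSet("t", {"g1", "g2", "g3"})
        ref = GeneSet("r", {f"g{i}" for i in range(4, 20)})
        catalog = AnnotationCatalog("ns", {
            "c1": {"g1", "g2", "g3"},
            "c2": {"g5", "g6"},
        })
        results = ora_analysis(test, ref, catalog, FilterConfig())
        by_cat = {r.category_id: r for r in results}
        # population restricted to annotated genes: 5 of them
        assert by_cat["c1"].N == 5
        assert by_cat["c1"].k == 3
        # BH family = both categories
        assert by_cat["c1"].p_adjusted >= by_cat["c1"].p_raw
        assert len(results) == 2

    def test_full_population_switch(self):
        test = GeneSet("t", {"g1", "g2"})
        ref = GeneSet("r", {f"g{i}" for i in range(3, 11)})
        catalog = AnnotationCatalog("ns", {"c1": {"g1", "g2"}})
        cfg = FilterConfig(restrict_population=False)
        (r,) = ora_analysis(test, ref, catalog, cfg)
        assert r.N == 10
        assert r.p_raw == pytest.approx(1 / 45, rel=1e-12)
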