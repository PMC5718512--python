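"""Null moments, z-score and Monte-Carlo normalisation, consensus voting."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import heatpath as hp
from heatpath import nullmodel


def enumerate_indicator_moments(n, k):
    """Brute-force moments of without-replacement indicators over all C(n,k) draws."""
    draws = list(itertools.combinations(range(n), k))
    x = np.zeros((len(draws), n))
    for row, combo in enumerate(draws):
        x[row, list(combo)] = 1.0
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, bias=True)
    return mean, cov


class TestInputMoments:
    def test_against_exhaustive_enumeration(self):
        mean, cov = enumerate_indicator_moments(10, 4)
        m = hp.null_input_moments(10, 4)
        np.testing.assert_allclose(mean, np.full(10, m.mean), atol=1e-12)
        np.testing.assert_allclose(np.diag(cov), np.full(10, m.var), atol=1e-12)
        off = cov[~np.eye(10, dtype=bool)]
        np.testing.assert_allclose(off, np.full(off.size, m.cov), atol=1e-12)
        assert m.mean == pytest.approx(0.4)
        assert m.var == pytest.approx(0.24)
        assert m.cov == pytest.approx(-0.24 / 9)

    def test_single_draw_against_enumeration(self):
        mean, cov = enumerate_indicator_moments(6, 1)
        m = hp.null_input_moments(6, 1)
        np.testing.assert_allclose(mean, np.full(6, m.mean), atol=1e-12)
        np.testing.assert_allclose(np.diag(cov), np.full(6, m.var), atol=1e-12)
        assert m.cov == pytest.approx(cov[0, 1])

    def test_full_draw_is_deterministic(self):
        m = hp.null_input_moments(7, 7)
        assert m.var == 0.0
        assert m.cov == 0.0

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            hp.null_input_moments(5, 6)
        with pytest.raises(ValueError):
            hp.null_input_moments(5, 0)

    @given(n=st.integers(2, 40), k=st.integers(1, 40))
    @settings(derandomize=True, max_examples=50)
    def test_covariance_rows_sum_to_zero(self, n, k):
        # sum of indicators is constant, so each covariance row sums to zero
        k = min(k, n)
        m = hp.null_input_moments(n, k)
        row_sum = m.var + (n - 1) * m.cov
        assert row_sum == pytest.approx(0.0, abs=1e-12)


class TestAnalyticNullMoments:
    def test_chain_single_compound_null_is_deterministic(self, chain_graph):
        system = hp.conductance_system(chain_graph)
        r = hp.heat_response_matrix(system)
        null = hp.analytic_null_moments(r, hp.null_input_moments(1, 1))
        np.testing.assert_allclose(null.mu, [3.0, 2.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(null.sigma, 0.0, atol=1e-12)
        assert null.degenerate.all()

    def test_ora_toy_pathway_null_is_hypergeometric(self, ora_toy):
        # temperature(A) == hit count, so its null moments must equal those of
        # Hypergeometric(N=10, K=3, n=4): mean 1.2, variance 0.56
        r = hp.heat_response_matrix(hp.conductance_system(ora_toy))
        null = hp.analytic_null_moments(r, hp.null_input_moments(10, 4))
        i = ora_toy.index["pw_A"]
        assert null.mu[i] == pytest.approx(1.2, abs=1e-9)
        assert null.sigma[i] ** 2 == pytest.approx(0.56, abs=1e-9)

    def test_empirical_null_matches_analytic(self, small_graph):
        system = hp.conductance_system(small_graph)
        r = hp.heat_response_matrix(system)
        n_in = 8
        null = hp.analytic_null_moments(r, hp.null_input_moments(len(small_graph.compounds), n_in))
        draws = hp.sample_null_scores(r, n_in, n_perm=4000, seed=9)
        emp_mean = draws.mean(axis=1)
        se = null.sigma / math.sqrt(draws.shape[1])
        ok = np.abs(emp_mean - null.mu) <= 4 * se + 1e-12
        assert ok.mean() >= 0.99

    def test_dimension_mismatch_rejected(self, ora_toy):
        r = hp.heat_response_matrix(hp.conductance_system(ora_toy))
        with pytest.raises(ValueError, match="compound columns"):
            hp.analytic_null_moments(r, hp.null_input_moments(7, 2))


class TestZScores:
    def test_score_at_null_mean_is_zero_and_degenerates_flagged(self, ora_toy, ora_toy_input):
        system = hp.conductance_system(ora_toy)
        r = hp.heat_response_matrix(system)
        null = hp.analytic_null_moments(r, hp.null_input_moments(10, 4))
        observed = hp.heat_diffusion_scores(system, ora_toy_input)
        at_mean = hp.ScoreVector(observed.node_ids, null.mu.copy(), "hd")
        z = hp.zscore_normalise(at_mean, null)
        np.testing.assert_allclose(z.z[~null.degenerate], 0.0, atol=1e-12)

    def test_zscore_of_pathway_with_two_hits(self, ora_toy, ora_toy_input):
        system = hp.conductance_system(ora_toy)
        r = hp.heat_response_matrix(system)
        null = hp.analytic_null_moments(r, hp.null_input_moments(10, 4))
        observed = hp.heat_diffusion_scores(system, ora_toy_input)
        z = hp.zscore_normalise(observed, null)
        i = ora_toy.index["pw_A"]
        assert z.z[i] == pytest.approx((2 - 1.2) / math.sqrt(0.56), abs=1e-9)

    def test_degenerate_sigma_gives_nan_not_inf(self, chain_graph):
        system = hp.conductance_system(chain_graph)
        r = hp.heat_response_matrix(system)
        null = hp.analytic_null_moments(r, hp.null_input_moments(1, 1))
        observed = hp.heat_diffusion_scores(system, hp.InputSet(frozenset({"c"})))
        z = hp.zscore_normalise(observed, null)
        assert np.isnan(z.z).all()
        assert not z.rankable_mask().any()


class TestMonteCarlo:
    def test_pvalue_formula_bounds(self, ora_toy, ora_toy_input):
        system = hp.conductance_system(ora_toy)
        observed = hp.heat_diffusion_scores(system, ora_toy_input)
        mc = hp.monte_carlo_pvalues(
            nullmodel.hd_scorer(system), ora_toy, 4, observed, n_perm=100, seed=0
        )
        assert mc.p.min() >= 1 / 101
        assert mc.p.max() <= 1.0

    def test_seeded_reproducibility_and_response_equivalence(self, ora_toy, ora_toy_input):
        system = hp.conductance_system(ora_toy)
        observed = hp.heat_diffusion_scores(system, ora_toy_input)
        r = hp.heat_response_matrix(system)
        a = hp.monte_carlo_pvalues(nullmodel.hd_scorer(system), ora_toy, 4, observed, 200, seed=7)
        b = hp.monte_carlo_pvalues(r, ora_toy, 4, observed, 200, seed=7)
        np.testing.assert_array_equal(a.p, b.p)
        c = hp.monte_carlo_pvalues(r, ora_toy, 4, observed, 200, seed=8)
        assert not np.array_equal(a.p, c.p)

    def test_exhaustive_null_equals_hypergeometric_tail(self, ora_toy, ora_toy_input):
        # all C(10,4) = 210 draws: P(temperature(A) >= 2) = 70/210 = 1/3
        system = hp.conductance_system(ora_toy)
        observed = hp.heat_diffusion_scores(system, ora_toy_input)
        r = hp.heat_response_matrix(system)
        exact = hp.exhaustive_pvalues(r, ora_toy, 4, observed)
        i = ora_toy.index["pw_A"]
        assert exact.meta["n_draws"] == 210
        assert exact.p[i] == pytest.approx(70 / 210, abs=1e-12)

    def test_monte_carlo_converges_to_exhaustive_tail(self, ora_toy, ora_toy_input):
        system = hp.conductance_system(ora_toy)
        observed = hp.heat_diffusion_scores(system, ora_toy_input)
        r = hp.heat_response_matrix(system)
        mc = hp.monte_carlo_pvalues(r, ora_toy, 4, observed, n_perm=4000, seed=1)
        i = ora_toy.index["pw_A"]
        assert mc.p[i] == pytest.approx(1 / 3, abs=0.03)

    def test_pvalues_uniform_under_the_null(self, small_graph):
        # inputs drawn from the null itself should give roughly uniform p
        from scipy import stats

        system = hp.conductance_system(small_graph)
        r = hp.heat_response_matrix(system)
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(40):
            chosen = rng.choice(len(small_graph.compounds), 6, replace=False)
            inp = hp.InputSet(frozenset(small_graph.compounds[i] for i in chosen))
            observed = hp.heat_diffusion_scores(system, inp)
            mc = hp.monte_carlo_pvalues(r, small_graph, 6, observed, n_perm=200, seed=int(rng.integers(2**31)))
            pvals.append(mc.p[small_graph.index[small_graph.pathways[0]]])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestConsensus:
    def test_strict_majority_with_nine_votes(self):
        solutions = [{"a", "b"}] * 5 + [{"b", "c"}] * 4
        kept = hp.consensus_vote(solutions, 9)
        assert kept == frozenset({"a", "b"})  # a in 5 >= 5; c in 4 < 5

    def test_single_vote_returns_the_solution(self):
        assert hp.consensus_vote([{"x", "y"}]) == frozenset({"x", "y"})

    def test_identical_solutions_preserve_size(self):
        sol = set(f"n{i}" for i in range(250))
        assert hp.consensus_vote([sol] * 9, 9) == frozenset(sol)

    def test_empty_solution_list_rejected(self):
        with pytest.raises(ValueError):
            hp.consensus_vote([])

    @given(st.lists(st.sets(st.sampled_from("abcdef")), min_size=1, max_size=9))
    @settings(derandomize=True, max_examples=50)
    def test_consensus_is_subset_of_union_and_contains_intersection(self, solutions):
        kept = hp.consensus_vote(solutions)
        union = set().union(*solutions)
        inter = set.intersection(*map(set, solutions))
        assert kept <= union
        assert inter <= kept
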