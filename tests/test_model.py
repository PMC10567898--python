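"""Estimator correctness: conjugate updates, posterior means, evidence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import gammaln
from scipy.stats import beta as beta_dist

from bacon import (
    BayesTransitionModel,
    ConstraintGraph,
    ConstraintViolationError,
    FrequentistTransitionModel,
    InteractionCounts,
    SyntheticSystem,
    default_alpha_grid,
    fit_bacon,
    fit_frequentist,
    fit_noninformative,
    frobenius_distance,
    log_marginal_likelihood,
    posterior_mean,
    sample_interactions,
    select_alpha,
    topology_baseline,
)


@pytest.fixture
def three_successor_graph():
    return ConstraintGraph(["i", "a", "b", "c"], [("i", "a"), ("i", "b"), ("i", "c")])


class TestFrequentist:
    def test_row_normalisation(self):
        counts = InteractionCounts({("i", "a"): 2, ("i", "c"): 1})
        T = fit_frequentist(counts, ["i", "a", "b", "c"])
        assert np.allclose(T.values[0], [0, 2 / 3, 0, 1 / 3])

    def test_single_observation_is_one_hot(self):
        T = fit_frequentist(InteractionCounts({("i", "a"): 1}), ["i", "a"])
        assert T.values[0, 1] == 1.0

    def test_zero_data_all_rows_undefined(self):
        T = fit_frequentist(InteractionCounts(), ["a", "b"])
        assert not T.defined.any()


class TestBaconPosterior:
    def test_conjugate_update_is_addition(self, three_successor_graph):
        counts = InteractionCounts({("i", "a"): 2, ("i", "c"): 1})
        post = fit_bacon(counts, three_successor_graph, alpha=1.0)
        succ, conc = post.row("i")
        assert succ == ("a", "b", "c")
        assert np.array_equal(conc, [3.0, 1.0, 2.0])

    def test_zero_data_recovers_prior(self, triangle_graph):
        post = fit_bacon(InteractionCounts(), triangle_graph, alpha=0.3)
        for i in range(3):
            assert np.array_equal(post.concentrations[i], [0.3, 0.3])

    def test_forbidden_pair_raises(self, two_successor_graph):
        counts = InteractionCounts({("a", "b"): 1})
        with pytest.raises(ConstraintViolationError, match="'a'"):
            fit_bacon(counts, two_successor_graph, alpha=1.0)

    def test_posterior_mean_formula(self, three_successor_graph):
        counts = InteractionCounts({("i", "a"): 2, ("i", "c"): 1})
        T = posterior_mean(fit_bacon(counts, three_successor_graph, 1.0))
        assert np.allclose(T.values[0], [0, 1 / 2, 1 / 6, 1 / 3])

    def test_prior_only_mean_is_uniform(self):
        g = ConstraintGraph(["i", *"wxyz"], [("i", s) for s in "wxyz"])
        for alpha in (0.05, 1.0, 7.0):
            T = posterior_mean(fit_bacon(InteractionCounts(), g, alpha))
            assert np.allclose(T.values[0][1:], 0.25)

    @settings(derandomize=True, max_examples=20)
    @given(st.lists(st.tuples(st.sampled_from(["a", "b", "c"]),
                              st.sampled_from(["a", "b", "c"])),
                    max_size=15))
    def test_conjugacy_split_invariance(self, pairs):
        """Fitting all data equals fitting half then updating with the rest."""
        nodes = ["a", "b", "c"]
        triangle_graph = ConstraintGraph(
            nodes, [(i, j) for i in nodes for j in nodes if i != j]
        )
        pairs = [(i, j) for i, j in pairs if i != j]
        half = len(pairs) // 2
        c_all = InteractionCounts.from_pairs(pairs)
        c1 = InteractionCounts.from_pairs(pairs[:half])
        c2 = InteractionCounts.from_pairs(pairs[half:])
        post_once = fit_bacon(c_all, triangle_graph, 1.0)
        post_twice = fit_bacon(c1, triangle_graph, 1.0).updated(c2)
        for a, b in zip(post_once.concentrations, post_twice.concentrations):
            assert np.array_equal(a, b)

    def test_monte_carlo_mean(self, three_successor_graph, rng):
        """Analytic mean sits within 3 SE of 1e5 posterior draws."""
        counts = InteractionCounts({("i", "a"): 2, ("i", "c"): 1})
        post = fit_bacon(counts, three_successor_graph, 1.0)
        _, conc = post.row("i")
        draws = rng.dirichlet(conc, size=100_000)
        se = draws.std(axis=0) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - conc / conc.sum()) < 3 * se)

    def test_large_sample_converges_to_frequentist(self):
        """At m=1e5 the posterior mean is within 1e-3 of the MLE."""
        nodes = [str(i) for i in range(8)]
        g = ConstraintGraph.complete(nodes)
        t_gt = np.full((8, 8), 1 / 7)
        np.fill_diagonal(t_gt, 0.0)
        from bacon.graph import TransitionMatrix

        system = SyntheticSystem(
            kind="erdos_renyi",
            constraint=g,
            t_gt=TransitionMatrix(t_gt, nodes, support=g),
            start_probs=np.full(8, 1 / 8),
        )
        counts = sample_interactions(system, 100_000, seed=4)
        bayes = posterior_mean(fit_bacon(counts, g, 1.0))
        mle = fit_frequentist(counts, nodes)
        assert np.max(np.abs(bayes.values - mle.values)) < 1e-3

    def test_consistency_error_decreases_with_data(self):
        """Frobenius distance to the truth shrinks as the sample grows."""
        from bacon import GeneratorConfig, generate_system

        system = generate_system(
            GeneratorConfig("erdos_renyi", n_nodes=20, n_edges=60), seed=9
        )
        errors = []
        for m in (100, 1_000, 10_000, 100_000):
            counts = sample_interactions(system, m, seed=m)
            T = posterior_mean(fit_bacon(counts, system.constraint, 1.0))
            errors.append(frobenius_distance(T, system.t_gt))
        assert all(a > b for a, b in zip(errors, errors[1:]))


class TestNoninformative:
    def test_equals_bacon_on_complete_graph(self):
        nodes = ["a", "b", "c"]
        counts = InteractionCounts({("a", "b"): 2, ("b", "c"): 1})
        p1 = fit_noninformative(counts, nodes)
        p2 = fit_bacon(counts, ConstraintGraph.complete(nodes), 1.0)
        for a, b in zip(p1.concentrations, p2.concentrations):
            assert np.array_equal(a, b)

    def test_zero_data_mean_uniform_over_others(self):
        T = posterior_mean(fit_noninformative(InteractionCounts(), ["a", "b", "c"]))
        assert np.allclose(T.values, (np.ones((3, 3)) - np.eye(3)) / 2)

    def test_self_loops_excluded_by_default(self):
        post = fit_noninformative(InteractionCounts({("a", "b"): 1}), ["a", "b"])
        succ, conc = post.row("a")
        assert succ == ("b",) and np.array_equal(conc, [2.0])

    def test_self_loops_optional(self):
        post = fit_noninformative(InteractionCounts(), ["a", "b"], self_loops=True)
        assert post.row("a")[0] == ("a", "b")


class TestTopologyBaseline:
    def test_star_is_uniform(self):
        g = ConstraintGraph(["hub", *"abcde"], [("hub", s) for s in "abcde"])
        T = topology_baseline(g)
        assert np.allclose(T.values[0][1:], 0.2)

    def test_equals_zero_data_bacon_for_any_alpha(self, triangle_graph):
        base = topology_baseline(triangle_graph)
        for alpha in (0.01, 10.0):
            zb = posterior_mean(fit_bacon(InteractionCounts(), triangle_graph, alpha))
            assert np.array_equal(base.values, zb.values)

    def test_chain_rows_are_one_hot(self):
        g = ConstraintGraph(["a", "b", "c"], [("a", "b"), ("b", "c")])
        T = topology_baseline(g)
        assert T.values[0, 1] == 1.0 and T.values[1, 2] == 1.0
        assert not T.defined[2]  # sink stays undefined


def _evidence_oracle_two_successors(n1, n2, alpha):
    """Numeric-integration evidence for one node with two successors."""
    z = np.exp(gammaln(n1 + n2 + 1) - gammaln(n1 + 1) - gammaln(n2 + 1))
    integral, _ = quad(
        lambda p: p**n1 * (1 - p) ** n2 * beta_dist.pdf(p, alpha, alpha), 0, 1
    )
    return np.log(z * integral)


class TestEvidence:
    @pytest.mark.parametrize(
        "n1,n2,alpha",
        [(1, 1, 1.0), (2, 0, 1.0), (5, 3, 1.0), (4, 4, 0.5), (7, 2, 2.5)],
    )
    def test_matches_numeric_integration(self, two_successor_graph, n1, n2, alpha):
        counts = InteractionCounts({("i", "a"): n1, ("i", "b"): n2})
        got = log_marginal_likelihood(counts, two_successor_graph, alpha)
        assert got == pytest.approx(
            _evidence_oracle_two_successors(n1, n2, alpha), abs=1e-8
        )

    def test_uniform_prior_examples_give_one_third(self, two_successor_graph):
        for pattern in ({("i", "a"): 1, ("i", "b"): 1}, {("i", "a"): 2}):
            got = log_marginal_likelihood(
                InteractionCounts(pattern), two_successor_graph, 1.0
            )
            assert got == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_zero_data_has_probability_one(self, triangle_graph):
        assert log_marginal_likelihood(InteractionCounts(), triangle_graph, 0.7) == 0.0

    @pytest.mark.parametrize("alpha", [0.3, 1.0, 2.5])
    @pytest.mark.parametrize("m", [1, 3, 5])
    def test_normalisation_over_count_configurations(
        self, two_successor_graph, alpha, m
    ):
        """Evidence sums to 1 over all (n1, m-n1) splits of m observations."""
        total = sum(
            np.exp(
                log_marginal_likelihood(
                    InteractionCounts({("i", "a"): n1, ("i", "b"): m - n1}),
                    two_successor_graph,
                    alpha,
                )
            )
            for n1 in range(m + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestSelectAlpha:
    def test_zero_data_ties_break_to_smallest(self, triangle_graph):
        table = select_alpha(InteractionCounts(), triangle_graph)
        assert np.allclose(table.log_evidence, 0.0)
        assert table.selected == pytest.approx(0.01)

    @pytest.mark.parametrize(
        "counts,expected",
        [({("i", "a"): 5, ("i", "b"): 5}, 2.0), ({("i", "a"): 10}, 0.5)],
    )
    def test_balanced_vs_biased_counts(self, two_successor_graph, counts, expected):
        """Balanced counts prefer the flatter prior, biased the peakier one."""
        grid = np.array([0.5, 2.0])
        table = select_alpha(InteractionCounts(counts), two_successor_graph, grid)
        # independent log-gamma oracle over both successors (zeros included)
        def lev(a):
            n = np.array(
                [counts.get(("i", "a"), 0), counts.get(("i", "b"), 0)], dtype=float
            )
            m = n.sum()
            z = gammaln(m + 1) - gammaln(n + 1).sum()
            return (
                z
                + (gammaln(a + n) - gammaln(a)).sum()
                + gammaln(2 * a)
                - gammaln(2 * a + m)
            )
        oracle = grid[int(np.argmax([lev(a) for a in grid]))]
        assert table.selected == expected == oracle

    def test_default_grid_shape(self):
        grid = default_alpha_grid()
        assert grid.size == 50
        assert grid[0] == pytest.approx(1e-2) and grid[-1] == pytest.approx(1e2)
        assert np.allclose(np.diff(np.log10(grid)), np.log10(grid[1] / grid[0]))


class TestModelObjects:
    def test_bayes_model_with_constraint(self, three_successor_graph):
        counts = InteractionCounts({("i", "a"): 2})
        res = BayesTransitionModel(counts, three_successor_graph).fit(alpha=1.0)
        assert "BaCon" in res.method
        assert res.transition_matrix.values[0, 1] == pytest.approx(3 / 5)
        assert "alpha" in res.summary()

    def test_bayes_model_without_constraint_is_noninformative(self):
        counts = InteractionCounts({("a", "b"): 1})
        res = BayesTransitionModel(counts, nodes=["a", "b", "c"]).fit()
        assert "noninformative" in res.method
        ref = posterior_mean(fit_noninformative(counts, ["a", "b", "c"]))
        assert np.array_equal(res.transition_matrix.values, ref.values)

    def test_alpha_selection_records_table(self, two_successor_graph):
        counts = InteractionCounts({("i", "a"): 8, ("i", "b"): 8})
        res = BayesTransitionModel(counts, two_successor_graph).fit(alpha="select")
        assert res.evidence_table is not None
        assert res.alpha == res.evidence_table.selected

    def test_frequentist_model_summary(self):
        counts = InteractionCounts({("a", "b"): 3})
        res = FrequentistTransitionModel(counts).fit()
        assert "frequentist" in res.method
        assert "Observations (m):  3" in res.summary()
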