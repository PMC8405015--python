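"""Trait likelihoods: transition matrices, pruning, MC and exact marginals."""

import itertools
import math

import numpy as np
import pytest

from xenorisk import (
    BinaryTraitModel,
    TraitCounts,
    genealogy_trait_likelihood,
    marginal_trait_likelihood_exact,
    marginal_trait_likelihood_mc,
    parse_extended_newick,
    sample_genealogy,
    transition_matrix,
)
from xenorisk.experiments import three_taxon_network
from xenorisk.network import NetworkError
from xenorisk.simulate import Genealogy

from oracles import enumerate_three_leaf, riemann_two_taxon, series_expm


def all_patterns(species):
    for states in itertools.product((0, 1), repeat=len(species)):
        yield TraitCounts.from_pattern(dict(zip(species, states)))


class TestModel:
    def test_normalization_makes_theta_the_rate(self):
        for ratio in (0.1, 1.0, 10.0):
            m = BinaryTraitModel.from_ratio(ratio)
            pi = m.stationary()
            assert pi[0] * m.u + pi[1] * m.v == pytest.approx(1.0)
            assert m.u / m.v == pytest.approx(ratio)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            BinaryTraitModel(0.0, 1.0)
        with pytest.raises(ValueError):
            BinaryTraitModel.from_ratio(-1)

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            TraitCounts({"A": (0, 0)})
        with pytest.raises(ValueError):
            TraitCounts({"A": (-1, 2)})
        with pytest.raises(ValueError):
            TraitCounts.from_pattern({"A": 2})


class TestTransitionMatrix:
    def test_zero_duration_is_identity(self, model):
        assert np.allclose(transition_matrix(model, 0.0), np.eye(2))

    def test_long_duration_reaches_stationarity(self):
        m = BinaryTraitModel.from_ratio(0.25, theta=1.0)
        p = transition_matrix(m, 1e6)
        pi = m.stationary()
        assert np.allclose(p, np.vstack([pi, pi]), atol=1e-12)

    @pytest.mark.parametrize("u,v,theta,t", [
        (1.0, 1.0, 0.01, 10.0),
        (2.0, 0.5, 0.003, 3.0),
        (0.1, 1.0, 1.0, 0.7),
    ])
    def test_matches_matrix_exponential(self, u, v, theta, t):
        m = BinaryTraitModel(u, v, normalize=False)
        a, b = theta * m.u, theta * m.v
        q = np.array([[-a, a], [b, -b]])
        assert np.allclose(transition_matrix(m, t, theta),
                           series_expm(q, t), atol=1e-12)

    def test_negative_duration_rejected(self, model):
        with pytest.raises(ValueError):
            transition_matrix(model, -1.0)


class TestGenealogyLikelihood:
    def test_single_leaf_gives_stationary(self):
        m = BinaryTraitModel.from_ratio(3.0, theta=0.01)
        gen = Genealogy([("A", 0), ("B", 0)], [2.0], [[0, 1]])
        pi = m.stationary()
        p0 = sum(genealogy_trait_likelihood(
            gen, TraitCounts.from_pattern({"A": 0, "B": s}), m)
            for s in (0, 1))
        assert p0 == pytest.approx(pi[0], abs=1e-12)

    def test_pattern_probabilities_sum_to_one(self, model):
        net = three_taxon_network()
        gen = sample_genealogy(net, {"A": 1, "B": 1, "C": 1}, rng_seed=2)
        total = sum(genealogy_trait_likelihood(gen, c, model)
                    for c in all_patterns(["A", "B", "C"]))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_state_enumeration_oracle(self):
        # fixed 3-leaf genealogy ((A,B)@0.8, C)@2.3, hand-composed sum over
        # the 4 internal/root state combinations
        m = BinaryTraitModel.from_ratio(0.5, theta=0.05)
        gen = Genealogy([("A", 0), ("B", 0), ("C", 0)],
                        [0.8, 2.3], [[0, 1], [3, 2]])
        a, b = m.rates()
        for (sa, sb, sc) in ((1, 1, 0), (0, 1, 1), (0, 0, 0)):
            want = enumerate_three_leaf(0.8, 2.3, sa, sb, sc, a, b,
                                        m.stationary())
            got = genealogy_trait_likelihood(
                gen, TraitCounts.from_pattern({"A": sa, "B": sb, "C": sc}), m)
            assert got == pytest.approx(want, rel=1e-12)

    def test_polymorphic_counts_sum_over_assignments(self, model):
        # two exchangeable B leaves with counts (1,1): the likelihood is the
        # sum of the two explicit leaf labellings
        gen = Genealogy([("A", 0), ("B", 0), ("B", 1)],
                        [0.5, 1.7], [[1, 2], [3, 0]])
        counts = TraitCounts({"A": (0, 1), "B": (1, 1)})
        got = genealogy_trait_likelihood(gen, counts, model)
        a, b = model.rates()
        pi = model.stationary()
        want = (enumerate_three_leaf(0.5, 1.7, 0, 1, 1, a, b, pi)
                + enumerate_three_leaf(0.5, 1.7, 1, 0, 1, a, b, pi))
        assert got == pytest.approx(want, rel=1e-12)

    def test_leaf_species_mismatch_errors(self, model):
        gen = Genealogy([("A", 0), ("B", 0)], [1.0], [[0, 1]])
        with pytest.raises(ValueError):
            genealogy_trait_likelihood(
                gen, TraitCounts.from_pattern({"A": 0, "C": 1}), model)


class TestExactMarginal:
    def test_tiny_theta_returns_root_state_prob(self):
        m = BinaryTraitModel.from_ratio(1.0, theta=1e-8)
        net = parse_extended_newick("((B:1,C:1):1,A:2);")
        est = marginal_trait_likelihood_exact(
            net, TraitCounts.from_pattern({"A": 0, "B": 0, "C": 0}), m)
        assert est.estimate == pytest.approx(m.stationary()[0], abs=1e-6)

    def test_two_taxon_matches_riemann_oracle(self):
        m = BinaryTraitModel.from_ratio(2.0, theta=0.02)
        net = parse_extended_newick("(A:1.5,B:1.5);")
        a, b = m.rates()
        for (sa, sb) in ((0, 1), (1, 1)):
            want = riemann_two_taxon(1.5, sa, sb, a, b, m.stationary())
            got = marginal_trait_likelihood_exact(
                net, TraitCounts.from_pattern({"A": sa, "B": sb}), m)
            assert got.estimate == pytest.approx(want, abs=1e-6)
            assert got.se == 0.0

    def test_pattern_sum_is_one(self, model):
        net = three_taxon_network(t1=1.0, t2=2.0, t_r=0.1, gamma=0.4)
        total = sum(marginal_trait_likelihood_exact(net, c, model).estimate
                    for c in all_patterns(["A", "B", "C"]))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_label_symmetry(self):
        # swapping u<->v and inverting all observed states is a relabelling
        net = three_taxon_network(gamma=0.3)
        m = BinaryTraitModel.from_ratio(5.0, theta=0.01)
        m_inv = BinaryTraitModel.from_ratio(0.2, theta=0.01)
        for states in ((1, 1, 0), (0, 1, 0)):
            direct = marginal_trait_likelihood_exact(
                net, TraitCounts.from_pattern(
                    dict(zip("ABC", states))), m)
            flipped = marginal_trait_likelihood_exact(
                net, TraitCounts.from_pattern(
                    {sp: 1 - s for sp, s in zip("ABC", states)}), m_inv)
            assert direct.estimate == pytest.approx(flipped.estimate,
                                                    rel=1e-9)

    def test_monomorphic_likelihood_nonincreasing_in_theta(self):
        # with u=v, more mutation makes the all-ancestral data less likely
        net = parse_extended_newick("((B:1,C:1):1,A:2);")
        counts = TraitCounts.from_pattern({"A": 0, "B": 0, "C": 0})
        prev = None
        for theta in np.linspace(0.0, 0.5, 20):
            m = BinaryTraitModel.from_ratio(1.0, theta=max(theta, 1e-9))
            val = marginal_trait_likelihood_exact(net, counts, m).estimate
            if prev is not None:
                assert val <= prev + 1e-12
            prev = val
        assert marginal_trait_likelihood_exact(
            net, counts, BinaryTraitModel.from_ratio(1.0, theta=1e-9)
        ).estimate == pytest.approx(0.5, abs=1e-6)

    def test_oversized_instances_rejected(self, model):
        big = parse_extended_newick("(((A:1,B:1):1,C:2):1,(D:1,E:1):2);")
        with pytest.raises(NetworkError):
            marginal_trait_likelihood_exact(
                big, TraitCounts.from_pattern(
                    {s: 0 for s in "ABCDE"}), model)
        net = three_taxon_network()
        with pytest.raises(NetworkError):
            marginal_trait_likelihood_exact(
                net, TraitCounts({"A": (0, 1), "B": (5, 5), "C": (1, 0)}),
                model)


class TestMonteCarloMarginal:
    def test_gamma_zero_network_equals_tree(self, model, three_taxon_pattern):
        net = three_taxon_network(gamma=0.0)
        tree = parse_extended_newick("((B:1,C:1):1,A:2);")
        e1 = marginal_trait_likelihood_mc(net, three_taxon_pattern, model,
                                          n_genealogies=20_000, rng_seed=1)
        e2 = marginal_trait_likelihood_mc(tree, three_taxon_pattern, model,
                                          n_genealogies=20_000, rng_seed=2)
        se = math.hypot(e1.se, e2.se)
        assert e1.estimate == pytest.approx(e2.estimate, abs=3 * se)

    def test_mc_matches_exact(self, model, three_taxon_pattern):
        net = three_taxon_network(t1=1.0, t2=11.0, t_r=0.1, gamma=0.5)
        exact = marginal_trait_likelihood_exact(net, three_taxon_pattern,
                                                model)
        mc = marginal_trait_likelihood_mc(net, three_taxon_pattern, model,
                                          n_genealogies=50_000, rng_seed=3)
        assert mc.estimate == pytest.approx(exact.estimate, abs=3 * mc.se)

    def test_mc_estimator_is_unbiased(self, model, three_taxon_pattern):
        # 100 independent small-n estimates scatter around the exact value
        net = three_taxon_network(gamma=0.4)
        exact = marginal_trait_likelihood_exact(net, three_taxon_pattern,
                                                model).estimate
        rng = np.random.default_rng(8)
        ests = [marginal_trait_likelihood_mc(
            net, three_taxon_pattern, model, n_genealogies=1000,
            rng_seed=rng).estimate for _ in range(100)]
        mean = np.mean(ests)
        se = np.std(ests, ddof=1) / 10.0
        assert mean == pytest.approx(exact, abs=3 * se)

    def test_polymorphic_mc_agrees_with_per_genealogy_pruning(self, model):
        # the vectorized batch evaluator and the reference pruning must agree
        # genealogy by genealogy
        from xenorisk.likelihood import (_batch_counts_likelihood,
                                         _leaf_partials)
        from xenorisk.simulate import sample_genealogies

        net = three_taxon_network()
        counts = TraitCounts({"A": (0, 1), "B": (7, 3), "C": (1, 0)})
        labels, ages, children = sample_genealogies(
            net, counts.sample_scheme(), 20, rng_seed=4)
        a, b = model.rates()
        batch = _batch_counts_likelihood(ages, children,
                                         _leaf_partials(labels, counts),
                                         a, b, model.stationary())
        for r in range(20):
            gen = Genealogy(labels, ages[r], children[r])
            ref = genealogy_trait_likelihood(gen, counts, model)
            assert batch[r] == pytest.approx(ref, rel=1e-10)

    def test_se_shrinks_with_n(self, model, three_taxon_pattern):
        net = three_taxon_network()
        small = marginal_trait_likelihood_mc(net, three_taxon_pattern, model,
                                             n_genealogies=500, rng_seed=5)
        large = marginal_trait_likelihood_mc(net, three_taxon_pattern, model,
                                             n_genealogies=50_000, rng_seed=5)
        assert large.se < small.se
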