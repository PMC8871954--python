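"""CTMC transition probabilities, pruning likelihood, ancestral marginals."""

import numpy as np
import pytest

from conftest import exhaustive_loglik, exhaustive_marginal, random_rate_matrix
from traitlab import simulate
from traitlab.ctmc import (PruningContext, RateMatrix, ancestral_marginals,
                           log_likelihood, read_trait_table, resolve_missing,
                           transition_probs, uniform_prior, stationary_prior)
from traitlab.tree import TreeError, read_newick, tag_mrca


class TestTransitionProbs:
    def test_t_zero_is_identity(self):
        Q = RateMatrix(k=3, rates={(0, 1): 1.0, (1, 2): 0.5, (2, 0): 0.2})
        assert np.allclose(transition_probs(Q, 0.0), np.eye(3))

    def test_symmetric_binary_stationary(self):
        Q = RateMatrix(k=2, rates={(0, 1): 1.0, (1, 0): 1.0})
        P = transition_probs(Q, 50.0)
        assert np.allclose(P, 0.5, atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = int(rng.integers(2, 5))
            Q = random_rate_matrix(rng, k)
            t = float(rng.exponential(0.5))
            P = transition_probs(Q, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert P.min() >= 0.0

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            Q = random_rate_matrix(rng, 3)
            s, t = rng.exponential(0.3, size=2)
            lhs = transition_probs(Q, s) @ transition_probs(Q, t)
            assert np.allclose(lhs, transition_probs(Q, s + t), atol=1e-9)

    def test_negative_time_rejected(self):
        Q = RateMatrix(k=2, rates={(0, 1): 1.0})
        with pytest.raises(ValueError):
            transition_probs(Q, -0.1)

    def test_rate_matrix_validation(self):
        with pytest.raises(ValueError, match="negative"):
            RateMatrix(k=2, rates={(0, 1): -1.0})
        with pytest.raises(ValueError, match="forbidden"):
            RateMatrix(k=2, rates={(0, 1): 1.0}, forbidden={(0, 1)})

    def test_stationary_prior(self):
        Q = RateMatrix(k=2, rates={(0, 1): 2.0, (1, 0): 1.0})
        pi = stationary_prior(Q)
        assert np.allclose(pi, [1 / 3, 2 / 3])
        assert np.allclose(pi @ Q.matrix(), 0.0, atol=1e-12)


class TestLogLikelihood:
    def test_no_rates_uniform_root(self, cherry3):
        Q = RateMatrix(k=2, rates={})
        tips = {x: frozenset({0}) for x in "ABC"}
        assert log_likelihood(cherry3, tips, Q) == pytest.approx(np.log(0.5))

    def test_matches_exhaustive_oracle_k3(self, quartet):
        rng = np.random.default_rng(3)
        tips = {"A": frozenset({0}), "B": frozenset({2}),
                "C": frozenset({1}), "D": frozenset({1, 2})}
        for _ in range(10):
            Q = random_rate_matrix(rng, 3)
            got = log_likelihood(quartet, tips, RateMatrix.from_matrix(Q))
            want = exhaustive_loglik(quartet, tips, Q, uniform_prior(3))
            assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_child_and_tip_order(self):
        t1 = read_newick("((A:0.3,B:0.4):0.2,(C:0.5,D:0.1):0.6);")
        t2 = read_newick("((D:0.1,C:0.5):0.6,(B:0.4,A:0.3):0.2);")
        Q = RateMatrix(k=2, rates={(0, 1): 1.7, (1, 0): 0.3})
        tips = {"A": {0}, "B": {1}, "C": {0}, "D": {1}}
        tips_rev = dict(reversed(list(tips.items())))
        assert log_likelihood(t1, tips, Q) == pytest.approx(
            log_likelihood(t2, tips_rev, Q), abs=1e-12)

    def test_missing_taxon_named(self, cherry3):
        Q = RateMatrix(k=2, rates={(0, 1): 1.0, (1, 0): 1.0})
        with pytest.raises(TreeError, match="C"):
            log_likelihood(cherry3, {"A": {0}, "B": {1}}, Q)

    def test_result_nonpositive(self):
        tree = simulate.simulate_tree(n_tips=30, seed=5)
        Q = RateMatrix(k=2, rates={(0, 1): 2.4, (1, 0): 0.1})
        tips, _ = simulate.simulate_trait(tree, Q, seed=6)
        assert log_likelihood(tree, tips, Q) <= 0.0


class TestAncestralMarginals:
    def test_no_rates_all_state0(self, cherry3):
        t = tag_mrca(cherry3, "anc", ["A", "B"])
        Q = RateMatrix(k=2, rates={})
        tips = {x: frozenset({0}) for x in "ABC"}
        assert np.allclose(ancestral_marginals(t, tips, Q, "anc"), [1.0, 0.0])

    def test_matches_restricted_enumeration(self, quartet):
        rng = np.random.default_rng(7)
        t = tag_mrca(quartet, "anc", ["A", "B"])
        tips = {"A": frozenset({0}), "B": frozenset({1}),
                "C": frozenset({2}), "D": frozenset({1, 2})}
        for _ in range(5):
            Q = random_rate_matrix(rng, 3)
            got = ancestral_marginals(t, tips, RateMatrix.from_matrix(Q), "anc")
            want = exhaustive_marginal(t, tips, Q, uniform_prior(3),
                                       t.node_tags["anc"])
            assert np.allclose(got, want, atol=1e-10)

    def test_all_nodes_sum_to_one(self):
        tree = simulate.simulate_tree(n_tips=40, seed=8)
        Q = RateMatrix(k=2, rates={(0, 1): 2.4, (1, 0): 0.1})
        tips, _ = simulate.simulate_trait(tree, Q, seed=9)
        ctx = PruningContext(tree, tips, 2)
        marg = ctx.node_marginals(Q.matrix())
        assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-9)

    def test_fully_ambiguous_tips_propagate_prior(self, cherry3, ambiguous_tips):
        # with no data the marginal at any node is the root prior pushed
        # through the transition matrices along the root-to-node path
        t = tag_mrca(cherry3, "root", ["A", "B", "C"])
        t = tag_mrca(t, "anc", ["A", "B"])
        Q = RateMatrix(k=2, rates={(0, 1): 1.3, (1, 0): 0.4})
        got_root = ancestral_marginals(t, ambiguous_tips, Q, "root")
        assert np.allclose(got_root, [0.5, 0.5], atol=1e-12)
        anc = t.node_tags["anc"]
        want = uniform_prior(2) @ transition_probs(Q, float(t.blen[anc]))
        got = ancestral_marginals(t, ambiguous_tips, Q, "anc")
        assert np.allclose(got, want, atol=1e-10)
        # symmetric rates preserve uniformity everywhere
        Qs = RateMatrix(k=2, rates={(0, 1): 0.9, (1, 0): 0.9})
        assert np.allclose(ancestral_marginals(t, ambiguous_tips, Qs, "anc"),
                           [0.5, 0.5], atol=1e-12)

    def test_untagged_node_rejected(self, cherry3, ambiguous_tips):
        Q = RateMatrix(k=2, rates={(0, 1): 1.0, (1, 0): 1.0})
        with pytest.raises(TreeError, match="tag"):
            ancestral_marginals(cherry3, ambiguous_tips, Q, "nope")


class TestTraitTable:
    def test_round_trip_with_ambiguity(self, tmp_path):
        p = tmp_path / "traits.tsv"
        p.write_text("taxA\t0\ntaxB\t12\ntaxC\t2\ntaxD\t-\n")
        tips = read_trait_table(p)
        assert tips["taxA"] == frozenset({0})
        assert tips["taxB"] == frozenset({1, 2})
        assert tips["taxD"] is None
        resolved = resolve_missing(tips, 3)
        assert resolved["taxD"] == frozenset({0, 1, 2})

    def test_bad_state_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("taxA\tx1\n")
        with pytest.raises(ValueError, match="bad state"):
            read_trait_table(p)
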