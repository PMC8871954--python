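"""MCMC engine: prior schemes, reverse-jump moves, stepping stone, Bayes factors."""

import numpy as np
import pytest
from scipy import stats

from traitlab import simulate
from traitlab.ctmc import RateMatrix
from traitlab.mcmc import (ChainSettings, MarginalLikelihood, RateModelSpec,
                           bayes_factor, evidence_label, model_spec,
                           sample_posterior, stepping_stone)
from traitlab.tree import read_newick


@pytest.fixture
def flat_tree():
    return read_newick("((A:0.1,B:0.1):0.1,C:0.2);")


@pytest.fixture
def flat_tips():
    return {x: frozenset({0, 1}) for x in "ABC"}


class TestSpecs:
    def test_scheme_presets(self):
        assert model_spec("E", 2).exp_mean == 10.0
        assert model_spec("H1", 2).hyper == (0.0, 10.0)
        assert model_spec("H2", 2).hyper == (0.0, 100.0)
        assert model_spec("R1", 2).reverse_jump
        assert model_spec("R2", 2).hyper == (0.0, 100.0)
        hb = model_spec("HBIASED", 2)
        assert hb.per_group_hyper == {0: (0.0, 1.0), 1: (1.0, 10.0)}
        assert hb.settings.n_chains == 100

    def test_validation(self):
        with pytest.raises(ValueError, match="scheme"):
            model_spec("X", 2)
        with pytest.raises(ValueError, match="lower < upper"):
            RateModelSpec(k=2, scheme="H1", hyper=(5.0, 5.0))
        with pytest.raises(ValueError, match="exceed burnin"):
            ChainSettings(iterations=100, burnin=100)
        with pytest.raises(ValueError, match="thinning"):
            ChainSettings(thinning=0)
        with pytest.raises(ValueError, match="biased"):
            model_spec("HBIASED", 3)


class TestPosteriorSampling:
    def test_flat_likelihood_recovers_prior_mean(self, flat_tree, flat_tips):
        spec = model_spec("E", 2)
        st = ChainSettings(iterations=60_000, burnin=10_000, thinning=10,
                           n_chains=1, seed=4)
        summ = sample_posterior(flat_tree, flat_tips, spec, settings=st)
        q01 = summ.rates[:, 0]
        se = 3 * q01.std() / np.sqrt(len(q01) / 10)  # crude ESS discount
        assert abs(q01.mean() - 10.0) < max(se, 0.8)

    def test_fixed_seed_is_bit_identical(self, flat_tree):
        tips = {"A": frozenset({0}), "B": frozenset({1}), "C": frozenset({0})}
        spec = model_spec("H1", 2)
        st = ChainSettings(iterations=5_000, burnin=1_000, thinning=10,
                           n_chains=2, seed=42)
        a = sample_posterior(flat_tree, tips, spec, settings=st)
        b = sample_posterior(flat_tree, tips, spec, settings=st)
        assert np.array_equal(a.rates, b.rates)
        assert np.array_equal(a.loglik, b.loglik)

    def test_taxon_input_order_irrelevant(self, flat_tree):
        tips = {"A": frozenset({0}), "B": frozenset({1}), "C": frozenset({0})}
        spec = model_spec("E", 2)
        st = ChainSettings(iterations=5_000, burnin=1_000, thinning=10,
                           n_chains=1, seed=3)
        a = sample_posterior(flat_tree, tips, spec, settings=st)
        b = sample_posterior(flat_tree, dict(reversed(list(tips.items()))),
                             spec, settings=st)
        assert np.array_equal(a.rates, b.rates)

    def test_node_probs_recorded_and_normalized(self, flat_tree):
        from traitlab.tree import tag_mrca
        t = tag_mrca(flat_tree, "anc", ["A", "B"])
        tips = {"A": frozenset({0}), "B": frozenset({0}), "C": frozenset({1})}
        spec = model_spec("E", 2)
        st = ChainSettings(iterations=4_000, burnin=1_000, thinning=10,
                           n_chains=1, seed=1)
        summ = sample_posterior(t, tips, spec, tags=("anc",), settings=st)
        probs = summ.node_probs["anc"]
        assert probs.shape == (300, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert summ.mean_node_probs("anc")[0] > 0.5  # both children in state 0

    def test_unknown_tag_rejected(self, flat_tree, flat_tips):
        with pytest.raises(ValueError, match="tag"):
            sample_posterior(flat_tree, flat_tips, model_spec("E", 2),
                             tags=("nope",))


class TestReverseJump:
    def test_structure_prior_uniform_under_flat_likelihood(self, flat_tree,
                                                           flat_tips):
        # binary trait: 4 structures (separate, merged, q01=0, q10=0) must be
        # equally likely a priori -- checks the dimension-matching bookkeeping
        spec = model_spec("R1", 2)
        st = ChainSettings(iterations=150_000, burnin=20_000, thinning=10,
                           n_chains=1, seed=5)
        summ = sample_posterior(flat_tree, flat_tips, spec, settings=st)
        q01, q10 = summ.rates[:, 0], summ.rates[:, 1]
        merged = float(((q01 == q10) & (q01 > 0)).mean())
        z01 = float((q01 == 0).mean())
        z10 = float((q10 == 0).mean())
        sep = 1.0 - merged - z01 - z10
        assert np.allclose([sep, merged, z01, z10], 0.25, atol=0.04)

    def test_asymmetric_truth_pins_slow_rate(self):
        # strongly asymmetric simulation: q10 ~ 0 should be pinned to zero far
        # more often than q01
        tree = simulate.simulate_tree(n_tips=200, seed=42)
        Q = RateMatrix(k=2, rates={(0, 1): 5.0, (1, 0): 0.01})
        tips, _ = simulate.simulate_trait(tree, Q, seed=43, root_state=0)
        spec = model_spec("R1", 2)
        st = ChainSettings(iterations=40_000, burnin=8_000, thinning=10,
                           n_chains=1, seed=9)
        summ = sample_posterior(tree, tips, spec, settings=st)
        assert summ.zero_fraction((1, 0)) > summ.zero_fraction((0, 1))
        assert summ.zero_fraction((1, 0)) > 0.5


class TestSteppingStone:
    def test_flat_likelihood_logml_zero(self, flat_tree, flat_tips):
        ml = stepping_stone(flat_tree, flat_tips, model_spec("E", 2),
                            stones=10, iterations=200, seed=3)
        assert isinstance(ml, MarginalLikelihood)
        assert abs(ml.logml) < 1e-9
        assert len(ml.stone_log_weights) == 10
        assert ml.betas[0] == 0.0 and ml.betas[-1] == 1.0

    def test_deterministic_given_seed(self, flat_tree):
        tips = {"A": frozenset({0}), "B": frozenset({1}), "C": frozenset({0})}
        a = stepping_stone(flat_tree, tips, model_spec("E", 2), stones=8,
                           iterations=150, seed=11)
        b = stepping_stone(flat_tree, tips, model_spec("E", 2), stones=8,
                           iterations=150, seed=11)
        assert a.logml == b.logml

    def test_monte_carlo_error_shrinks_with_iterations(self):
        # doubling iterations per stone should shrink the replicate SD by
        # about sqrt(2); allow generous slack around that scaling
        tree = read_newick("(A:0.5,B:0.5);")
        tips = {"A": frozenset({0}), "B": frozenset({1})}
        spec = model_spec("E", 2, exp_mean=1.0)
        sds = []
        for iters in (150, 600):  # 4x, so expected SD ratio = 2
            vals = [stepping_stone(tree, tips, spec, stones=8, iterations=iters,
                                   seed=s).logml for s in range(10)]
            sds.append(np.std(vals))
        assert sds[1] < sds[0]
        # 4x iterations: at least the sqrt(2) gain of a doubling, and not
        # implausibly more than ~6x (burnin effects shift it off exactly 2)
        assert 1.4 < sds[0] / sds[1] < 6.0


class TestBayesFactor:
    def test_zero_and_labels(self):
        bf, label = bayes_factor(-10.0, -10.0)
        assert bf == 0.0 and label == "none"
        bf, label = bayes_factor(-7.0, -10.0)
        assert bf == pytest.approx(6.0) and label == "strong"

    @pytest.mark.parametrize("bf,label", [
        (1.9, "none"), (2.5, "positive"), (5.0, "strong"), (9.9, "strong"),
        (12.0, "strong-to-very-strong"), (25.0, "very strong"),
    ])
    def test_threshold_table(self, bf, label):
        assert evidence_label(bf) == label

    def test_antisymmetric(self):
        a, _ = bayes_factor(-5.0, -8.0)
        b, _ = bayes_factor(-8.0, -5.0)
        assert a == -b

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(np.inf, 0.0)
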