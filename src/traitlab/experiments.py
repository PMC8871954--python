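"""Self-contained validation experiments on synthetic data.

Each function runs one calibration or cross-check experiment end to end —
generating its own inputs, running the inference machinery, and measuring
the result — and returns plain numbers.  The reference computations used
here (exhaustive state enumeration, closed forms, grid quadrature) do not
share code with the pruning/MCMC paths they check.

Problem sizes are desk-scale: chains of ~10^5 iterations, 16-24 stepping
stones, 20 replicates per calibration.  See docs/methods.md for the
rationale behind each experimental design.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from scipy.linalg import expm

from . import mcmc, simulate, traits
from .ctmc import PruningContext, RateMatrix, transition_probs, uniform_prior
from .mcmc import ChainSettings, model_spec, sample_posterior, stepping_stone
from .patterns import pattern_table
from .synteny import (encode_karyotype, fitch_state_sets,
                      reconstruct_ancestral_adjacencies)
from .tree import RootedTree, read_newick

__all__ = [
    "pruning_oracle_check",
    "closed_form_check",
    "prior_recovery_check",
    "quadrature_check",
    "rate_recovery_check",
    "correlation_calibration",
    "adjacency_parsimony_check",
    "pattern_recovery_check",
    "demo_membrane_reconstruction",
]


# -- reference computations ---------------------------------------------------

def _enumeration_loglik(tree: RootedTree, tips: dict, Q: np.ndarray,
                        prior: np.ndarray) -> float:
    """Likelihood by brute-force summation over internal-node states."""
    k = Q.shape[0]
    internal = [v for v in tree.postorder() if not tree.is_tip(v)]
    P = {v: expm(Q * tree.blen[v]) for v in range(tree.n_nodes)
         if tree.parent[v] >= 0}
    tipstate = {v: sorted(tips[tree.tip_labels[v]]) for v in tree.tips()}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for combo in itertools.product(*(tipstate[v] for v in tree.tips())):
            state.update(dict(zip(tree.tips(), combo)))
            p = prior[state[tree.root]]
            for v in range(tree.n_nodes):
                if tree.parent[v] >= 0:
                    p *= P[v][state[int(tree.parent[v])], state[v]]
            total += p
    return float(np.log(total))


def _hyper_mixture_cdf(lo: float, hi: float, n_grid: int = 2000):
    """CDF of an exponential rate whose mean is Uniform(lo, hi)."""
    eps = (hi - lo) * 1e-9 + 1e-12
    m = np.linspace(lo + eps, hi, n_grid)

    def F(q):
        q = np.atleast_1d(np.asarray(q, float))
        surv = np.trapezoid(np.exp(-q[:, None] / m[None, :]), m, axis=1) / (hi - lo)
        return 1.0 - surv

    return F


def _exhaustive_min_change_sets(tree: RootedTree, tip_states: dict) -> dict:
    internal = [v for v in tree.postorder() if not tree.is_tip(v)]
    tipv = {v: tip_states[tree.tip_labels[v]] for v in tree.tips()}
    best, achieving = None, {}
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assign))
        state.update(tipv)
        changes = sum(state[v] != state[int(tree.parent[v])]
                      for v in range(tree.n_nodes) if tree.parent[v] >= 0)
        if best is None or changes < best:
            best = changes
            achieving = {v: {state[v]} for v in range(tree.n_nodes)}
        elif changes == best:
            for v in range(tree.n_nodes):
                achieving[v].add(state[v])
    return {v: frozenset(s) for v, s in achieving.items()}


# -- experiment 1: pruning vs enumeration --------------------------------------

def pruning_oracle_check(seed: int = 0, n_draws: int = 100) -> dict:
    """Max |pruning - enumeration| log-likelihood over random small problems."""
    rng = np.random.default_rng(seed)
    worst, n_done = 0.0, 0
    while n_done < n_draws:
        for n_tips in (3, 4, 5, 6):
            for k in (2, 3):
                tree = simulate.simulate_tree(n_tips=n_tips,
                                              seed=int(rng.integers(2 ** 31)))
                Q = rng.exponential(2.0, size=(k, k))
                np.fill_diagonal(Q, 0.0)
                np.fill_diagonal(Q, -Q.sum(axis=1))
                tips = {}
                for tax in tree.taxa:
                    if rng.random() < 0.15:  # occasional ambiguity set
                        tips[tax] = frozenset(rng.choice(k, size=2, replace=False)
                                              .tolist())
                    else:
                        tips[tax] = frozenset({int(rng.integers(k))})
                ctx = PruningContext(tree, tips, k)
                got = ctx.loglik(Q)
                want = _enumeration_loglik(tree, tips, Q, uniform_prior(k))
                worst = max(worst, abs(got - want))
                n_done += 1
    return {"max_abs_diff": worst, "n": n_done}


# -- experiment 2: binary closed form ------------------------------------------

def closed_form_check() -> dict:
    """transition_probs against the two-state closed form on a rate x t grid."""
    worst, n = 0.0, 0
    for q01 in (0.01, 0.1, 0.5, 2.4, 10.0):
        for q10 in (0.01, 0.1, 0.5, 2.4, 10.0):
            Q = RateMatrix(k=2, rates={(0, 1): q01, (1, 0): q10})
            for t in (0.0, 0.01, 0.1, 0.5, 1.0, 5.0):
                P = transition_probs(Q, t)
                s = q01 + q10
                p01 = q01 / s * (1.0 - np.exp(-s * t))
                p10 = q10 / s * (1.0 - np.exp(-s * t))
                worst = max(worst, abs(P[0, 1] - p01), abs(P[1, 0] - p10),
                            abs(P[0, 0] - (1 - p01)), abs(P[1, 1] - (1 - p10)))
                n += 1
    return {"max_abs_diff": worst, "n": n}


# -- experiment 3: prior recovery ----------------------------------------------

def prior_recovery_check(seed: int = 0, n_samples: int = 10_000) -> dict:
    """Flat-likelihood MCMC must reproduce each scheme's marginal prior on q01.

    For the reverse-jump schemes the continuous check uses the first
    *n_samples* non-zero retained draws (the marginal prior there carries an
    atom at zero from pinned rates).
    """
    tree = read_newick("((A:0.1,B:0.1):0.1,C:0.2);")
    tips = {x: frozenset({0, 1}) for x in "ABC"}
    results = {}
    for i, scheme in enumerate(("E", "H1", "H2", "R1", "R2")):
        rj = scheme.startswith("R")
        # the shared hyper mean is the slow mode: thin harder when present
        thin = 15 if scheme == "E" else 40
        keep = int(n_samples * 1.8) if rj else n_samples
        st = ChainSettings(iterations=10_000 + keep * thin, burnin=10_000,
                           thinning=thin, n_chains=1, seed=seed + i)
        summ = sample_posterior(tree, tips, model_spec(scheme, 2), settings=st)
        q01 = summ.rates[:, summ.pairs.index((0, 1))]
        if rj:
            q01 = q01[q01 > 0][:n_samples]
        if scheme == "E":
            cdf = stats.expon(scale=10.0).cdf
        else:
            lo, hi = model_spec(scheme, 2).hyper
            cdf = _hyper_mixture_cdf(lo, hi)
        results[scheme] = float(stats.kstest(q01, cdf).statistic)
    return {"ks": results, "max_ks": max(results.values()), "n": n_samples}


# -- experiment 4: quadrature oracle --------------------------------------------

def quadrature_check(seed: int = 0) -> dict:
    """Two-tip binary fixture: posterior rate means and stepping-stone log
    marginal likelihood against dense 2-D grid quadrature."""
    t_branch, prior_mean = 0.5, 1.0
    tree = read_newick(f"(A:{t_branch},B:{t_branch});")
    tips = {"A": frozenset({0}), "B": frozenset({1})}

    g = np.linspace(1e-6, 20.0, 1500)
    qa, qb = np.meshgrid(g, g, indexing="ij")
    s = qa + qb
    e = np.exp(-s * t_branch)
    p00, p01 = (qb + qa * e) / s, qa * (1 - e) / s
    p10, p11 = qb * (1 - e) / s, (qa + qb * e) / s
    like = 0.5 * (p00 * p01 + p10 * p11)  # uniform root, tips (0, 1)
    prior = np.exp(-(qa + qb) / prior_mean) / prior_mean ** 2
    post = like * prior
    z = np.trapezoid(np.trapezoid(post, g, axis=1), g)
    mean01 = float(np.trapezoid(np.trapezoid(post * qa, g, axis=1), g) / z)
    mean10 = float(np.trapezoid(np.trapezoid(post * qb, g, axis=1), g) / z)
    logml = float(np.log(z))

    spec = model_spec("E", 2, exp_mean=prior_mean)
    st = ChainSettings(iterations=320_000, burnin=20_000, thinning=5,
                       n_chains=1, seed=seed)
    summ = sample_posterior(tree, tips, spec, settings=st)
    err01 = abs(summ.rate_mean((0, 1)) - mean01)
    err10 = abs(summ.rate_mean((1, 0)) - mean10)
    ml = stepping_stone(tree, tips, spec, stones=50, iterations=2000,
                        seed=seed + 1)
    return {"rate_mean_max_abs_err": max(err01, err10),
            "logml_abs_err": abs(ml.logml - logml),
            "quadrature_logml": logml, "n": summ.rates.shape[0]}


# -- experiment 5: parameter recovery --------------------------------------------

def rate_recovery_check(seed: int = 0, reps: int = 20, n_tips: int = 85,
                        iterations: int = 110_000) -> dict:
    """Credible-interval coverage for traits simulated at the inferred
    membrane-trait rate magnitudes (gain 2.4, loss 0.1).

    The generating model matches the inference model: the root state is
    drawn from the root prior; rates are fixed at the truth.  Inference uses
    the hyperprior scheme H1.  Returns the fraction of (rate, replicate)
    pairs whose central 95% interval covers the truth.
    """
    truth = {(0, 1): 2.4, (1, 0): 0.1}
    Q = RateMatrix(k=2, rates=truth)
    spec = model_spec("H1", 2)
    covered, n_checks = 0, 0
    for rep in range(reps):
        tree = simulate.simulate_tree(n_tips=n_tips, seed=seed + 100 + rep)
        tips, _ = simulate.simulate_trait(tree, Q, seed=seed + 200 + rep)
        st = ChainSettings(iterations=iterations, burnin=10_000, thinning=25,
                           n_chains=1, seed=seed + 300 + rep)
        summ = sample_posterior(tree, tips, spec, settings=st)
        for pair, tv in truth.items():
            lo, _, hi = summ.rate_quantiles(pair)
            covered += int(lo <= tv <= hi)
            n_checks += 1
    return {"coverage_pct": 100.0 * covered / n_checks, "n": n_checks}


# -- experiment 6: correlation calibration ----------------------------------------

def correlation_calibration(seed: int = 0, reps: int = 20, n_tips: int = 200,
                            stones: int = 16, iterations: int = 500) -> dict:
    """Power and null behaviour of the dependent-vs-independent Bayes factor.

    Dependent replicates use a strongly coupled 8-rate truth; independent
    replicates use matched marginal rates with no coupling.  Reports the
    fraction of dependent replicates with BF > 2 (positive evidence) and the
    median BF under independence.
    """
    dep_bfs, ind_bfs = [], []
    for rep in range(reps):
        tree = simulate.simulate_tree(n_tips=n_tips, seed=seed + 1000 + rep)
        t1, t2, _ = simulate.simulate_dependent_pair(
            tree, simulate.dependent_truth(), seed=seed + 2000 + rep)
        res = traits.correlation_test(tree, t1, t2, stones=stones,
                                      iterations=iterations,
                                      seed=seed + 3000 + rep)
        dep_bfs.append(res.bf)
        u1, u2, _ = simulate.simulate_dependent_pair(
            tree, simulate.independent_truth(), seed=seed + 4000 + rep)
        res0 = traits.correlation_test(tree, u1, u2, stones=stones,
                                       iterations=iterations,
                                       seed=seed + 5000 + rep)
        ind_bfs.append(res0.bf)
    return {"power_pct": 100.0 * float(np.mean(np.array(dep_bfs) > 2.0)),
            "null_median_bf": float(np.median(ind_bfs)),
            "dependent_bfs": dep_bfs, "independent_bfs": ind_bfs, "n": reps}


# -- experiment 7: adjacency parsimony ---------------------------------------------

def adjacency_parsimony_check(seed: int = 0, reps: int = 20,
                              p_escape: float = 0.05,
                              p_loss: float = 0.0) -> dict:
    """Two checks: per-adjacency minimum-change state sets against brute
    force on 6-leaf problems, and ancestral adjacency recovery on simulated
    gene-order evolution.

    The recovery bound is conditioned on the cluster-escape probability
    alone, so losses default to off here; adding gene loss removes genes
    (and both their adjacencies) from descendants outright, which bounds
    what any reconstruction can recover — pass ``p_loss`` to measure that
    information-limited regime too.
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    for rep in range(12):
        tree = simulate.simulate_tree(n_tips=6, seed=seed + 50 + rep)
        tip_states = {tax: int(rng.integers(2)) for tax in tree.taxa}
        got = fitch_state_sets(tree, tip_states)
        want = _exhaustive_min_change_sets(tree, tip_states)
        mismatches += sum(got[v] != want[v] for v in range(tree.n_nodes))

    recov = []
    for rep in range(reps):
        tree = simulate.simulate_tree(n_tips=16, seed=seed + 500 + rep)
        table, _, true_adjs = simulate.simulate_gene_orders(
            tree, p_escape=p_escape, p_loss=p_loss, seed=seed + 600 + rep)
        kars = {g: encode_karyotype(sub) for g, sub in table.groupby("genome")}
        rec = reconstruct_ancestral_adjacencies(tree, kars)
        for v in range(tree.n_nodes):
            if tree.is_tip(v) or not true_adjs[v]:
                continue
            hit = len(true_adjs[v] & rec.adjacencies[v]) / len(true_adjs[v])
            recov.append(hit)
    return {"oracle_mismatches": mismatches,
            "recovery_pct": 100.0 * float(np.mean(recov)), "n": reps}


# -- experiment 8: pattern recovery --------------------------------------------------

def pattern_recovery_check(seed: int = 0, reps: int = 20,
                           noise: float = 0.05) -> dict:
    """Fraction of phyla assigned their generating pattern at flip noise 5%."""
    correct, total = 0, 0
    for rep in range(reps):
        mat, pmap, truth = simulate.simulate_presence_matrix(
            noise=noise, seed=seed + rep)
        table = pattern_table(mat, pmap)
        for phylum, pid in truth.items():
            correct += int(table.loc[phylum, "pattern"] == str(pid))
            total += 1
    return {"recovery_pct": 100.0 * correct / total, "n": total}


# -- headline synthetic reconstruction -------------------------------------------------

def demo_membrane_reconstruction(seed: int = 0, n_tips: int = 85,
                                 iterations: int = 110_000,
                                 reps: int = 5) -> dict:
    """Membrane-trait reconstruction on synthetic 85-taxon datasets.

    Simulates a monoderm root with the inferred gain/loss magnitudes, then
    reconstructs the root state under scheme E; averaged over *reps*
    independent datasets (a single draw is dominated by the realized trait
    pattern).  Returns the mean root monoderm probability (percent) and the
    mean posterior rates — the synthetic analogue of the headline
    ancestral-state table.
    """
    from .tree import tag_mrca
    Q = RateMatrix(k=2, rates={(0, 1): 2.4, (1, 0): 0.1})
    p0s, q01s, q10s = [], [], []
    for rep in range(reps):
        tree = simulate.simulate_tree(n_tips=n_tips, seed=seed + 11 + 31 * rep)
        tips, states = simulate.simulate_trait(tree, Q,
                                               seed=seed + 12 + 31 * rep,
                                               root_state=0)
        tree = tag_mrca(tree, "LBCA", sorted(tree.taxa))
        st = ChainSettings(iterations=iterations, burnin=10_000, thinning=100,
                           n_chains=2, seed=seed + 13 + 31 * rep)
        summ = sample_posterior(tree, tips, model_spec("E", 2),
                                tags=("LBCA",), settings=st)
        p0s.append(float(summ.mean_node_probs("LBCA")[0]))
        q01s.append(summ.rate_mean((0, 1)))
        q10s.append(summ.rate_mean((1, 0)))
    return {"mean_P0_pct": 100.0 * float(np.mean(p0s)),
            "mean_q01": float(np.mean(q01s)),
            "mean_q10": float(np.mean(q10s)),
            "n": n_tips * reps}
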