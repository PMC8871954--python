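"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's computational paths:
likelihoods by exhaustive enumeration over internal-node states with
scipy expm, parsimony by brute-force minimum-change enumeration.
"""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from traitlab.tree import RootedTree, read_newick


# -- exhaustive likelihood oracle -------------------------------------------

def exhaustive_loglik(tree: RootedTree, tips: dict, Q: np.ndarray,
                      prior: np.ndarray) -> float:
    """Sum over all internal-node state assignments of products of
    transition probabilities (expm per edge)."""
    k = Q.shape[0]
    internal = [v for v in tree.postorder() if not tree.is_tip(v)]
    P = {v: expm(Q * tree.blen[v]) for v in range(tree.n_nodes)
         if tree.parent[v] >= 0}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for combo in itertools.product(*(sorted(tips[tree.tip_labels[v]])
                                         for v in tree.tips())):
            state.update(dict(zip(tree.tips(), combo)))
            p = prior[state[tree.root]]
            for v in range(tree.n_nodes):
                if tree.parent[v] >= 0:
                    p *= P[v][state[int(tree.parent[v])], state[v]]
            total += p
    return float(np.log(total))


def exhaustive_marginal(tree: RootedTree, tips: dict, Q: np.ndarray,
                        prior: np.ndarray, node: int) -> np.ndarray:
    """Exhaustive joint probability restricted to each fixed state at *node*,
    normalized."""
    k = Q.shape[0]
    out = np.zeros(k)
    if tree.is_tip(node):
        allowed = tips[tree.tip_labels[node]]
    for s in range(k):
        if tree.is_tip(node):
            if s not in allowed:
                continue
            restricted = dict(tips)
            restricted[tree.tip_labels[node]] = frozenset({s})
            out[s] = np.exp(exhaustive_loglik(tree, restricted, Q, prior))
        else:
            internal = [v for v in tree.postorder() if not tree.is_tip(v)]
            P = {v: expm(Q * tree.blen[v]) for v in range(tree.n_nodes)
                 if tree.parent[v] >= 0}
            total = 0.0
            others = [v for v in internal if v != node]
            for assign in itertools.product(range(k), repeat=len(others)):
                state = dict(zip(others, assign))
                state[node] = s
                for combo in itertools.product(
                        *(sorted(tips[tree.tip_labels[v]]) for v in tree.tips())):
                    state.update(dict(zip(tree.tips(), combo)))
                    p = prior[state[tree.root]]
                    for v in range(tree.n_nodes):
                        if tree.parent[v] >= 0:
                            p *= P[v][state[int(tree.parent[v])], state[v]]
                    total += p
            out[s] = total
    return out / out.sum()


# -- brute-force parsimony oracle --------------------------------------------

def exhaustive_mpr_sets(tree: RootedTree, tip_states: dict) -> dict:
    """Per-node sets of states attained in some minimum-change assignment,
    by enumerating every full labeling of the internal nodes."""
    internal = [v for v in tree.postorder() if not tree.is_tip(v)]
    tipv = {v: tip_states[tree.tip_labels[v]] for v in tree.tips()}
    best = None
    achieving: dict[int, set] = {v: set() for v in range(tree.n_nodes)}
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


def random_rate_matrix(rng: np.random.Generator, k: int, scale: float = 2.0) -> np.ndarray:
    Q = rng.exponential(scale, size=(k, k))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# -- fixtures ------------------------------------------------------------------

@pytest.fixture
def cherry3():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet():
    return read_newick("((A:0.3,B:0.4):0.2,(C:0.5,D:0.1):0.6);")


@pytest.fixture
def ambiguous_tips():
    return {x: frozenset({0, 1}) for x in "ABC"}
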