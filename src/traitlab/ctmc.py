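"""Continuous-time Markov models for k-state discrete traits on rooted trees.

Implements the MultiState machinery shared by all rate-prior schemes: rate
matrices (generators), transition probabilities ``P(t) = expm(Q t)``,
Felsenstein pruning log-likelihoods with ambiguity-aware tip partials, and
marginal ancestral state posteriors at tagged nodes (up/down algorithm).

The model is deliberately non-reversible: all off-diagonal rates are free
unless structurally forbidden (e.g. simultaneous double transitions in the
two-trait dependent/independent models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import expm

from .tree import RootedTree, TreeError

__all__ = [
    "RateMatrix",
    "TipStates",
    "uniform_prior",
    "stationary_prior",
    "transition_probs",
    "log_likelihood",
    "ancestral_marginals",
    "PruningContext",
    "read_trait_table",
    "write_bayestraits_data",
]

TipStates = dict  # taxon name -> frozenset of allowed states


@dataclass
class RateMatrix:
    """A k-state CTMC generator with named off-diagonal rates.

    ``rates[(i, j)]`` is the instantaneous rate q_ij (per unit branch
    length) of moving from state i to state j.  Pairs in ``forbidden`` are
    structural zeros and may not carry a rate.  The diagonal is implied
    (negative row sum).
    """

    k: int
    rates: dict[tuple[int, int], float] = field(default_factory=dict)
    forbidden: frozenset = frozenset()

    def __post_init__(self):
        self.forbidden = frozenset(self.forbidden)
        for (i, j), q in self.rates.items():
            if i == j or not (0 <= i < self.k and 0 <= j < self.k):
                raise ValueError(f"invalid rate index ({i},{j}) for k={self.k}")
            if (i, j) in self.forbidden:
                raise ValueError(f"rate ({i},{j}) is structurally forbidden")
            if q < 0:
                raise ValueError(f"negative rate q{i}{j}={q}")

    @property
    def free_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i in range(self.k) for j in range(self.k)
                if i != j and (i, j) not in self.forbidden]

    def matrix(self) -> np.ndarray:
        """The generator as a dense array (rows sum to zero)."""
        Q = np.zeros((self.k, self.k))
        for (i, j), q in self.rates.items():
            Q[i, j] = q
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    @classmethod
    def from_matrix(cls, Q: np.ndarray, forbidden=frozenset()) -> "RateMatrix":
        k = Q.shape[0]
        rates = {(i, j): float(Q[i, j]) for i in range(k) for j in range(k)
                 if i != j and (i, j) not in forbidden and Q[i, j] != 0.0}
        return cls(k=k, rates=rates, forbidden=forbidden)


def uniform_prior(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


def stationary_prior(Q: RateMatrix | np.ndarray) -> np.ndarray:
    """Stationary distribution of the chain (left null vector of Q)."""
    A = Q.matrix() if isinstance(Q, RateMatrix) else np.asarray(Q, float)
    k = A.shape[0]
    # solve pi Q = 0, sum(pi) = 1
    M = np.vstack([A.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def transition_probs(Q: RateMatrix | np.ndarray, t: float) -> np.ndarray:
    """Transition probability matrix ``P(t) = expm(Q t)``.

    Computed by scipy's scaling-and-squaring Pade expm; valid for any
    generator (no reversibility or diagonalizability assumption).
    """
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    A = Q.matrix() if isinstance(Q, RateMatrix) else np.asarray(Q, float)
    P = expm(A * t)
    return np.clip(P, 0.0, None)


# -- vectorized edge transition matrices ----------------------------------

def _edge_matrices_binary(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Closed-form 2-state P(t) for every edge length in *ts*."""
    a, b = Q[0, 1], Q[1, 0]
    s = a + b
    P = np.empty((len(ts), 2, 2))
    if s == 0.0:
        P[:] = np.eye(2)
        return P
    e = np.exp(-s * ts)
    P[:, 0, 0] = (b + a * e) / s
    P[:, 0, 1] = a * (1.0 - e) / s
    P[:, 1, 0] = b * (1.0 - e) / s
    P[:, 1, 1] = (a + b * e) / s
    return P


@njit(cache=True)
def _pmat_from_eig(w, V, Vinv, ts):  # pragma: no cover
    """P(t) = Re(V diag(e^{w t}) V^-1) for every t; returns (P, max row error)."""
    E, k = ts.shape[0], w.shape[0]
    P = np.empty((E, k, k))
    ew = np.empty(k, dtype=np.complex128)
    err = 0.0
    for e in range(E):
        for l in range(k):
            ew[l] = np.exp(w[l] * ts[e])
        for i in range(k):
            rowsum = 0.0
            for j in range(k):
                acc = 0.0 + 0.0j
                for l in range(k):
                    acc += V[i, l] * ew[l] * Vinv[l, j]
                x = acc.real
                if x < 0.0:
                    if x < -1e-9:
                        err = 1.0
                    x = 0.0
                P[e, i, j] = x
                rowsum += x
            d = abs(rowsum - 1.0)
            if d > err:
                err = d
    return P, err


def _edge_matrices_general(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """P(t) for every edge, via eigendecomposition with an expm fallback."""
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        P, err = _pmat_from_eig(w.astype(np.complex128), V.astype(np.complex128),
                                Vinv.astype(np.complex128), ts)
        if err < 1e-8:
            return P
    except np.linalg.LinAlgError:
        pass
    # rare: defective or ill-conditioned generator
    uniq, inv = np.unique(ts, return_inverse=True)
    Pu = np.stack([np.clip(expm(Q * t), 0.0, None) for t in uniq])
    return Pu[inv]


def edge_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    if Q.shape[0] == 2:
        return _edge_matrices_binary(Q, ts)
    return _edge_matrices_general(Q, ts)


# -- pruning kernel --------------------------------------------------------

@njit(cache=True)
def _prune_kernel(order, kids, kptr, P, part, root, prior):  # pragma: no cover
    k = part.shape[1]
    logscale = 0.0
    for idx in range(order.shape[0]):
        v = order[idx]
        for i in range(k):
            part[v, i] = 1.0
        for ci in range(kptr[v], kptr[v + 1]):
            c = kids[ci]
            for i in range(k):
                m = 0.0
                for j in range(k):
                    m += P[c, i, j] * part[c, j]
                part[v, i] *= m
        mx = 0.0
        for i in range(k):
            if part[v, i] > mx:
                mx = part[v, i]
        if mx <= 0.0:
            return -np.inf
        for i in range(k):
            part[v, i] /= mx
        logscale += np.log(mx)
    tot = 0.0
    for i in range(k):
        tot += prior[i] * part[root, i]
    if tot <= 0.0:
        return -np.inf
    return np.log(tot) + logscale


class PruningContext:
    """Precomputed tree arrays for repeated likelihood evaluation.

    Built once per (tree, tip data, k) combination; ``loglik`` is then cheap
    enough for MCMC inner loops.  Tip ambiguity sets enter as 0/1 indicator
    partials and are never renormalized.
    """

    def __init__(self, tree: RootedTree, tips: TipStates, k: int,
                 root_prior: np.ndarray | None = None):
        tree.validate()
        self.tree = tree
        self.k = k
        self.root = tree.root
        self.prior = uniform_prior(k) if root_prior is None else np.asarray(root_prior, float)
        if self.prior.shape != (k,) or abs(self.prior.sum() - 1.0) > 1e-9 or self.prior.min() < 0:
            raise ValueError("root prior must be a length-k probability vector")

        n = tree.n_nodes
        missing = [tree.tip_labels[v] for v in tree.tips() if tree.tip_labels[v] not in tips]
        if missing:
            raise TreeError(f"taxa missing from trait data: {sorted(missing)}")

        post = tree.postorder()
        self.order = np.array([v for v in post if not tree.is_tip(v)], dtype=np.int64)
        kids_flat: list[int] = []
        kptr = np.zeros(n + 1, dtype=np.int64)
        for v in range(n):
            kids_flat.extend(tree.children[v])
            kptr[v + 1] = len(kids_flat)
        self.kids = np.array(kids_flat, dtype=np.int64)
        self.kptr = kptr
        self.elen = tree.blen.astype(float).copy()

        self.part = np.zeros((n, k))
        for v in tree.tips():
            states = frozenset(tips[tree.tip_labels[v]])
            if not states or not states <= set(range(k)):
                raise ValueError(
                    f"tip {tree.tip_labels[v]!r}: states {set(states)} not a "
                    f"non-empty subset of 0..{k - 1}")
            for s in states:
                self.part[v, s] = 1.0

    # -- likelihood -------------------------------------------------------
    def loglik(self, Q: np.ndarray) -> float:
        P = edge_matrices(Q, self.elen)
        return float(_prune_kernel(self.order, self.kids, self.kptr, P,
                                   self.part, self.root, self.prior))

    # -- marginal ancestral states ----------------------------------------
    def node_marginals(self, Q: np.ndarray) -> np.ndarray:
        """Marginal posterior P(state | tips, Q) for every node, rows sum to 1."""
        tree = self.tree
        n, k = tree.n_nodes, self.k
        P = edge_matrices(Q, self.elen)
        up = self.part.copy()
        msg = np.zeros((n, k))  # message from node v to its parent
        for v in tree.postorder():
            if not tree.is_tip(v):
                up[v] = 1.0
                for c in tree.children[v]:
                    up[v] *= msg[c]
            s = up[v].sum()
            if s > 0:
                up[v] /= s
            if tree.parent[v] >= 0:
                msg[v] = P[v] @ up[v]
        down = np.zeros((n, k))
        down[self.root] = self.prior
        for u in tree.preorder():
            for v in tree.children[u]:
                outer = down[u].copy()
                for w in tree.children[u]:
                    if w != v:
                        outer *= msg[w]
                down[v] = outer @ P[v]
                s = down[v].sum()
                if s > 0:
                    down[v] /= s
        marg = up * down
        tot = marg.sum(axis=1, keepdims=True)
        tot[tot == 0.0] = 1.0
        return marg / tot


def log_likelihood(tree: RootedTree, tips: TipStates, Q: RateMatrix,
                   root_prior: np.ndarray | None = None) -> float:
    """Felsenstein pruning log-likelihood of tip data under generator *Q*."""
    ctx = PruningContext(tree, tips, Q.k, root_prior)
    return ctx.loglik(Q.matrix())


def ancestral_marginals(tree: RootedTree, tips: TipStates, Q: RateMatrix,
                        node: str, root_prior: np.ndarray | None = None) -> np.ndarray:
    """Marginal state probabilities at the tagged node *node*."""
    if node not in tree.node_tags:
        raise TreeError(f"node tag {node!r} not set on tree")
    ctx = PruningContext(tree, tips, Q.k, root_prior)
    return ctx.node_marginals(Q.matrix())[tree.node_tags[node]]


# -- trait table I/O -------------------------------------------------------

def read_trait_table(path) -> TipStates:
    """Read a two-column TSV ``taxon<TAB>state``.

    A state is one digit, or a concatenation of digits for an ambiguity set
    (the BayesTraits convention: ``12`` means {thin, thick} peptidoglycan).
    ``-`` or ``?`` denote a fully missing observation (all states allowed,
    resolved at likelihood time against the model's k).
    """
    out: TipStates = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
            taxon, state = fields
            if state in ("-", "?"):
                out[taxon] = None  # resolved by caller knowing k
            else:
                if not state.isdigit():
                    raise ValueError(f"{path}:{ln}: bad state {state!r}")
                out[taxon] = frozenset(int(ch) for ch in state)
    return out


def resolve_missing(tips: TipStates, k: int) -> TipStates:
    full = frozenset(range(k))
    return {t: (full if s is None else frozenset(s)) for t, s in tips.items()}


def write_bayestraits_data(tips: TipStates, path) -> None:
    """Write a BayesTraits-compatible two-column data file (for cross-checks)."""
    with open(path, "w") as fh:
        for taxon in sorted(tips):
            states = tips[taxon]
            code = "-" if states is None else "".join(str(s) for s in sorted(states))
            fh.write(f"{taxon}\t{code}\n")
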