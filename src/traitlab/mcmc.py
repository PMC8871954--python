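"""Bayesian inference of CTMC transition rates on a fixed rooted tree.

Implements the five MultiState prior schemes used for the cell-wall traits
plus the purposely biased sensitivity scheme:

======== ==============================================================
scheme   prior on each transition rate q_ij
======== ==============================================================
E        Exponential with mean 10 (fixed)
H1       Exponential whose mean is itself Uniform(0, 10) (hyperprior)
H2       Exponential, mean Uniform(0, 100)
R1       as H1, plus reverse-jump over rate-model structures
R2       as H2, plus reverse-jump
HBIASED  two-rate (binary) scheme with per-rate hyperpriors: the gain
         rate mean Uniform(0, 1) and the loss rate mean Uniform(1, 10),
         i.e. biased toward loss of the derived state
======== ==============================================================

Reverse-jump moves let the sampler tie distinct rates into shared classes
and/or pin rates to zero, with a uniform prior over model structures.  New
dimensions are born from the rate prior, so Jacobians are unity and the
prior density of the born rate cancels in the acceptance ratio.

Marginal likelihoods are estimated with the stepping-stone sampler over a
ladder of power posteriors; Bayes factors are reported on the doubled-log
scale with the conventional evidence labels (>2 positive, 5-10 strong,
>20 very strong).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .ctmc import PruningContext, TipStates, uniform_prior
from .tree import RootedTree

__all__ = [
    "ChainSettings",
    "RateModelSpec",
    "model_spec",
    "PosteriorSummary",
    "MarginalLikelihood",
    "sample_posterior",
    "stepping_stone",
    "bayes_factor",
    "evidence_label",
    "SCHEMES",
]

SCHEMES = ("E", "H1", "H2", "R1", "R2", "HBIASED")


@dataclass
class ChainSettings:
    """MCMC run lengths.  Defaults follow the full-scale analysis settings
    (1,100,000 cycles, sample every 1000, burnin 100,000, 10 chains)."""

    iterations: int = 1_100_000
    burnin: int = 100_000
    thinning: int = 1000
    n_chains: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= self.burnin:
            raise ValueError("iterations must exceed burnin")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class RateModelSpec:
    """A k-state rate model: tying structure, prior scheme, chain settings.

    ``groups`` ties off-diagonal (i, j) pairs into base parameters (the
    dependent/independent two-trait models use this); by default every
    allowed pair is its own parameter.  Reverse-jump then operates on top of
    the base groups.
    """

    k: int
    scheme: str = "E"
    groups: tuple[tuple[tuple[int, int], ...], ...] | None = None
    forbidden: frozenset = frozenset()
    exp_mean: float = 10.0
    hyper: tuple[float, float] | None = None
    per_group_hyper: dict[int, tuple[float, float]] | None = None
    reverse_jump: bool = False
    root_prior: np.ndarray | None = None
    settings: ChainSettings = field(default_factory=ChainSettings)

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.groups is None:
            pairs = [(i, j) for i in range(self.k) for j in range(self.k)
                     if i != j and (i, j) not in self.forbidden]
            self.groups = tuple((p,) for p in pairs)
        seen: set = set()
        for g in self.groups:
            for p in g:
                if p in seen:
                    raise ValueError(f"pair {p} appears in two groups")
                seen.add(p)
        for bounds in ([self.hyper] if self.hyper else []) + list(
                (self.per_group_hyper or {}).values()):
            lo, hi = bounds
            if not lo < hi:
                raise ValueError("hyperprior interval must have lower < upper")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [p for g in self.groups for p in g]


def model_spec(scheme: str, k: int, *, forbidden=frozenset(), groups=None,
               settings: ChainSettings | None = None, exp_mean: float = 10.0,
               root_prior=None) -> RateModelSpec:
    """Build the named prior scheme for a k-state trait."""
    scheme = scheme.upper()
    kwargs: dict = dict(k=k, scheme=scheme, forbidden=frozenset(forbidden),
                        groups=groups, exp_mean=exp_mean, root_prior=root_prior)
    if scheme == "E":
        pass
    elif scheme == "H1":
        kwargs["hyper"] = (0.0, 10.0)
    elif scheme == "H2":
        kwargs["hyper"] = (0.0, 100.0)
    elif scheme == "R1":
        kwargs.update(hyper=(0.0, 10.0), reverse_jump=True)
    elif scheme == "R2":
        kwargs.update(hyper=(0.0, 100.0), reverse_jump=True)
    elif scheme == "HBIASED":
        if k != 2:
            raise ValueError("the biased sensitivity scheme is a binary-trait scheme")
        kwargs["groups"] = (((0, 1),), ((1, 0),))
        kwargs["per_group_hyper"] = {0: (0.0, 1.0), 1: (1.0, 10.0)}
        st = settings or ChainSettings()
        settings = replace(st, n_chains=100)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if settings is not None:
        kwargs["settings"] = settings
    return RateModelSpec(**kwargs)


# -- results containers ----------------------------------------------------

@dataclass
class PosteriorSummary:
    """Pooled retained samples across chains, plus summaries.

    ``rates`` has one column per base pair (in ``pairs`` order); node state
    probabilities are per tagged node, one row per retained sample.
    """

    pairs: list[tuple[int, int]]
    rates: np.ndarray                      # (n_samples, n_pairs)
    hyper_means: np.ndarray | None         # (n_samples, n_hyper) or None
    loglik: np.ndarray                     # (n_samples,)
    chain: np.ndarray                      # (n_samples,) chain index
    node_probs: dict[str, np.ndarray]      # tag -> (n_samples, k)
    acceptance: dict[str, float]
    convergence: float                     # max standardized chain-mean discrepancy

    def rate_mean(self, pair) -> float:
        return float(self.rates[:, self.pairs.index(tuple(pair))].mean())

    def rate_quantiles(self, pair, qs=(0.025, 0.5, 0.975)) -> np.ndarray:
        col = self.rates[:, self.pairs.index(tuple(pair))]
        return np.quantile(col, qs)

    def zero_fraction(self, pair) -> float:
        col = self.rates[:, self.pairs.index(tuple(pair))]
        return float((col == 0.0).mean())

    def mean_node_probs(self, tag: str) -> np.ndarray:
        return self.node_probs[tag].mean(axis=0)

    def to_frame(self):
        import pandas as pd
        data = {"chain": self.chain, "loglik": self.loglik}
        for idx, (i, j) in enumerate(self.pairs):
            data[f"q{i}{j}"] = self.rates[:, idx]
        if self.hyper_means is not None:
            for h in range(self.hyper_means.shape[1]):
                data[f"hyper_mean_{h}"] = self.hyper_means[:, h]
        for tag, probs in self.node_probs.items():
            for s in range(probs.shape[1]):
                data[f"{tag}_P{s}"] = probs[:, s]
        return pd.DataFrame(data)


@dataclass
class MarginalLikelihood:
    logml: float
    stone_log_weights: np.ndarray   # per-stone log mean importance weight
    betas: np.ndarray               # full ladder including 0 and 1


# -- the sampler -----------------------------------------------------------

class _State:
    """Partition of base groups into rate classes (+ a zero set) with rates."""

    __slots__ = ("classes", "rates", "zero", "m")

    def __init__(self, classes, rates, zero, m):
        self.classes: list[list[int]] = classes   # lists of group indices
        self.rates: list[float] = rates            # one rate per class
        self.zero: list[int] = zero                # group indices pinned to 0
        self.m: np.ndarray = m                     # hyper means (may be len 0)


class _Sampler:
    def __init__(self, ctx: PruningContext, spec: RateModelSpec,
                 rng: np.random.Generator, beta: float = 1.0):
        self.ctx = ctx
        self.spec = spec
        self.rng = rng
        self.beta = beta
        self.k = spec.k
        self.groups = [list(g) for g in spec.groups]
        G = len(self.groups)
        # hyper means
        if spec.per_group_hyper:
            self.hyper_bounds = [spec.per_group_hyper[g] for g in range(G)]
        elif spec.hyper:
            self.hyper_bounds = [spec.hyper]
        else:
            self.hyper_bounds = []
        m = np.array([rng.uniform(lo, hi) for lo, hi in self.hyper_bounds])
        rates = [self._draw_prior_rate(m, g) for g in range(G)]
        self.state = _State(classes=[[g] for g in range(G)], rates=rates,
                            zero=[], m=m)
        self.sigma = 1.0          # log-scale step for rate moves
        self.hyper_w = [0.2 * (hi - lo) for lo, hi in self.hyper_bounds]
        self._tune = True
        self.n_acc = {"rate": 0, "hyper": 0, "rj": 0}
        self.n_try = {"rate": 0, "hyper": 0, "rj": 0}
        self._acc_window = [0, 0]
        self.ll = self._loglik()

    # -- priors ------------------------------------------------------------
    def _prior_mean(self, class_groups, m) -> float:
        spec = self.spec
        if spec.per_group_hyper:
            # per-group hyper implies no RJ (classes are single groups)
            return float(m[class_groups[0]])
        if spec.hyper:
            return float(m[0])
        return spec.exp_mean

    def _draw_prior_rate(self, m, group: int) -> float:
        mean = self._prior_mean([group], m)
        return float(self.rng.exponential(mean)) if mean > 0 else 0.0

    def _log_prior_rates(self, state: _State) -> float:
        lp = 0.0
        for cls, r in zip(state.classes, state.rates):
            mean = self._prior_mean(cls, state.m)
            if mean <= 0 or r < 0:
                return -np.inf
            lp += -math.log(mean) - r / mean
        return lp

    # -- likelihood ----------------------------------------------------------
    def _Q(self, state: _State | None = None) -> np.ndarray:
        state = state or self.state
        Q = np.zeros((self.k, self.k))
        for cls, r in zip(state.classes, state.rates):
            for g in cls:
                for (i, j) in self.groups[g]:
                    Q[i, j] = r
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def _loglik(self, state: _State | None = None) -> float:
        return self.ctx.loglik(self._Q(state))

    # -- moves ---------------------------------------------------------------
    def step(self):
        spec = self.spec
        u = self.rng.random()
        has_hyper = bool(self.hyper_bounds)
        can_rj = spec.reverse_jump and len(self.groups) > 1
        p_hyper = 0.2 if has_hyper else 0.0
        p_rj = 0.3 if can_rj else 0.0
        if u < p_hyper:
            self._move_hyper()
        elif u < p_hyper + p_rj:
            self._move_rj()
        else:
            self._move_rate()

    def _move_rate(self):
        st = self.state
        self.n_try["rate"] += 1
        self._acc_window[1] += 1
        c = int(self.rng.integers(len(st.classes)))
        r_old = st.rates[c]
        r_new = r_old * math.exp(self.sigma * self.rng.standard_normal())
        mean = self._prior_mean(st.classes[c], st.m)
        d_prior = (-(r_new - r_old) / mean) + (math.log(r_new) - math.log(r_old))
        st.rates[c] = r_new
        ll_new = self._loglik()
        log_alpha = self.beta * (ll_new - self.ll) + d_prior
        if math.log(self.rng.random()) < log_alpha:
            self.ll = ll_new
            self.n_acc["rate"] += 1
            self._acc_window[0] += 1
        else:
            st.rates[c] = r_old
        if self._tune and self._acc_window[1] >= 50:
            acc = self._acc_window[0] / self._acc_window[1]
            if acc < 0.2:
                self.sigma *= 0.8
            elif acc > 0.4:
                self.sigma *= 1.25
            self._acc_window = [0, 0]

    def _move_hyper(self):
        st = self.state
        self.n_try["hyper"] += 1
        h = int(self.rng.integers(len(self.hyper_bounds)))
        lo, hi = self.hyper_bounds[h]
        m_new = st.m[h] + self.rng.uniform(-self.hyper_w[h], self.hyper_w[h])
        if m_new < lo:
            m_new = 2 * lo - m_new
        elif m_new > hi:
            m_new = 2 * hi - m_new
        lp_old = self._log_prior_rates(st)
        m_save = st.m[h]
        st.m[h] = m_new
        lp_new = self._log_prior_rates(st)
        if math.log(self.rng.random()) < lp_new - lp_old:
            self.n_acc["hyper"] += 1
        else:
            st.m[h] = m_save

    # reverse-jump: split / merge / pin-to-zero / restore-from-zero
    def _rj_available(self, st: _State) -> list[str]:
        avail = []
        if any(len(c) >= 2 for c in st.classes):
            avail.append("split")
        if len(st.classes) >= 2:
            avail.append("merge")
            avail.append("tozero")
        if st.zero:
            avail.append("fromzero")
        return avail

    def _move_rj(self):
        st = self.state
        self.n_try["rj"] += 1
        avail = self._rj_available(st)
        move = avail[int(self.rng.integers(len(avail)))]
        log_psel = -math.log(len(avail))
        if move == "split":
            ok = self._rj_split(st, log_psel)
        elif move == "merge":
            ok = self._rj_merge(st, log_psel)
        elif move == "tozero":
            ok = self._rj_tozero(st, log_psel)
        else:
            ok = self._rj_fromzero(st, log_psel)
        if ok:
            self.n_acc["rj"] += 1

    def _try_state(self, new: _State, log_hastings: float) -> bool:
        ll_new = self._loglik(new)
        log_alpha = self.beta * (ll_new - self.ll) + log_hastings
        if math.log(self.rng.random()) < log_alpha:
            self.state = new
            self.ll = ll_new
            return True
        return False

    def _rj_split(self, st: _State, log_psel: float) -> bool:
        splittable = [i for i, c in enumerate(st.classes) if len(c) >= 2]
        ci = splittable[int(self.rng.integers(len(splittable)))]
        cls = st.classes[ci]
        s = len(cls)
        while True:
            mask = self.rng.random(s) < 0.5
            if 0 < mask.sum() < s:
                break
        keep = [g for g, mkeep in zip(cls, ~mask) if mkeep]
        new_grp = [g for g, mnew in zip(cls, mask) if mnew]
        mean = self._prior_mean(new_grp, st.m)
        r_new = float(self.rng.exponential(mean))
        classes = [list(c) for c in st.classes]
        classes[ci] = keep
        classes.append(new_grp)
        rates = list(st.rates) + [r_new]
        new = _State(classes, rates, list(st.zero), st.m)
        K_new = len(classes)
        avail_rev = self._rj_available(new)
        # forward: choose "split", the class, then which groups leave with the
        # fresh rate (2^s - 2 ordered outcomes); the born rate's prior cancels
        log_fwd = log_psel - math.log(len(splittable)) - math.log(2.0 ** s - 2.0)
        # reverse: choose "merge", the pair, the surviving rate
        log_rev = (-math.log(len(avail_rev)) - math.log(K_new * (K_new - 1) / 2.0)
                   - math.log(2.0))
        return self._try_state(new, log_rev - log_fwd)

    def _rj_merge(self, st: _State, log_psel: float) -> bool:
        K = len(st.classes)
        a, b = self.rng.choice(K, size=2, replace=False)
        a, b = int(a), int(b)
        survivor = a if self.rng.random() < 0.5 else b
        merged = list(st.classes[a]) + list(st.classes[b])
        classes = [list(c) for i, c in enumerate(st.classes) if i not in (a, b)]
        rates = [r for i, r in enumerate(st.rates) if i not in (a, b)]
        classes.append(merged)
        rates.append(st.rates[survivor])
        new = _State(classes, rates, list(st.zero), st.m)
        avail_rev = self._rj_available(new)
        s = len(merged)
        n_split_rev = sum(1 for c in classes if len(c) >= 2)
        log_fwd = log_psel - math.log(K * (K - 1) / 2.0) - math.log(2.0)
        log_rev = (-math.log(len(avail_rev)) - math.log(n_split_rev)
                   - math.log(2.0 ** s - 2.0))
        return self._try_state(new, log_rev - log_fwd)

    def _rj_tozero(self, st: _State, log_psel: float) -> bool:
        K = len(st.classes)
        ci = int(self.rng.integers(K))
        classes = [list(c) for i, c in enumerate(st.classes) if i != ci]
        rates = [r for i, r in enumerate(st.rates) if i != ci]
        zero = list(st.zero) + list(st.classes[ci])
        new = _State(classes, rates, zero, st.m)
        avail_rev = self._rj_available(new)
        z_new = len(zero)
        log_fwd = log_psel - math.log(K)
        log_rev = -math.log(len(avail_rev)) - math.log(2.0 ** z_new - 1.0)
        return self._try_state(new, log_rev - log_fwd)

    def _rj_fromzero(self, st: _State, log_psel: float) -> bool:
        z = len(st.zero)
        while True:
            mask = self.rng.random(z) < 0.5
            if mask.sum() > 0:
                break
        revived = [g for g, m_ in zip(st.zero, mask) if m_]
        zero = [g for g, m_ in zip(st.zero, mask) if not m_]
        mean = self._prior_mean(revived, st.m)
        r_new = float(self.rng.exponential(mean))
        classes = [list(c) for c in st.classes] + [revived]
        rates = list(st.rates) + [r_new]
        new = _State(classes, rates, zero, st.m)
        avail_rev = self._rj_available(new)
        K_new = len(classes)
        log_fwd = log_psel - math.log(2.0 ** z - 1.0)
        log_rev = -math.log(len(avail_rev)) - math.log(K_new)
        return self._try_state(new, log_rev - log_fwd)

    # -- bookkeeping ---------------------------------------------------------
    def pair_rates(self) -> np.ndarray:
        st = self.state
        out = np.zeros(len(self.spec.pairs))
        pos = {p: i for i, p in enumerate(self.spec.pairs)}
        for cls, r in zip(st.classes, st.rates):
            for g in cls:
                for p in self.groups[g]:
                    out[pos[p]] = r
        return out

    def freeze_tuning(self):
        self._tune = False


# -- public entry points ----------------------------------------------------

def sample_posterior(tree: RootedTree, tips: TipStates, spec: RateModelSpec,
                     tags: tuple[str, ...] = (),
                     settings: ChainSettings | None = None) -> PosteriorSummary:
    """Metropolis-Hastings (plus reverse-jump where enabled) posterior sampling.

    Each retained sample records the per-pair rates, the hyperprior mean(s)
    where applicable, the log-likelihood, and the marginal ancestral state
    probabilities at every tagged node under the sampled rates.  Chains are
    pooled for the summaries; a per-chain mean-discrepancy diagnostic is
    reported and a warning is emitted if chains disagree.
    """
    settings = settings or spec.settings
    for tag in tags:
        if tag not in tree.node_tags:
            raise ValueError(f"node tag {tag!r} not set on tree")
    ctx = PruningContext(tree, tips, spec.k, spec.root_prior)
    n_keep = (settings.iterations - settings.burnin) // settings.thinning
    n_hyper = (len(spec.groups) if spec.per_group_hyper
               else (1 if spec.hyper else 0))

    all_rates, all_hyper, all_ll, all_chain = [], [], [], []
    all_node: dict[str, list] = {t: [] for t in tags}
    acc_tot = {"rate": 0, "hyper": 0, "rj": 0}
    try_tot = {"rate": 0, "hyper": 0, "rj": 0}

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    for chain_id, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        sampler = _Sampler(ctx, spec, rng)
        for it in range(settings.iterations):
            if it == settings.burnin:
                sampler.freeze_tuning()
            sampler.step()
            if it >= settings.burnin and (it - settings.burnin) % settings.thinning == settings.thinning - 1:
                all_rates.append(sampler.pair_rates())
                if n_hyper:
                    all_hyper.append(sampler.state.m.copy())
                all_ll.append(sampler.ll)
                all_chain.append(chain_id)
                if tags:
                    marg = ctx.node_marginals(sampler._Q())
                    for t in tags:
                        all_node[t].append(marg[tree.node_tags[t]])
        for key in acc_tot:
            acc_tot[key] += sampler.n_acc[key]
            try_tot[key] += sampler.n_try[key]

    rates = np.array(all_rates).reshape(-1, len(spec.pairs))
    chain = np.array(all_chain, dtype=int)
    ll = np.array(all_ll)
    hyper = np.array(all_hyper) if n_hyper else None
    node_probs = {t: np.array(v) for t, v in all_node.items()}
    acceptance = {k: (acc_tot[k] / try_tot[k] if try_tot[k] else np.nan)
                  for k in acc_tot}

    # convergence: largest standardized discrepancy of a chain mean from the
    # pooled mean, over rate parameters
    conv = 0.0
    if settings.n_chains > 1 and len(rates):
        pooled_mean = rates.mean(axis=0)
        pooled_sd = rates.std(axis=0)
        pooled_sd[pooled_sd == 0.0] = 1.0
        for c in range(settings.n_chains):
            sub = rates[chain == c]
            if len(sub):
                conv = max(conv, float(np.max(np.abs(sub.mean(axis=0) - pooled_mean) / pooled_sd)))
        if conv > 0.5:
            warnings.warn(
                f"chains disagree (max standardized chain-mean discrepancy "
                f"{conv:.2f}); consider longer runs", RuntimeWarning)

    assert len(rates) == n_keep * settings.n_chains
    return PosteriorSummary(pairs=list(spec.pairs), rates=rates,
                            hyper_means=hyper, loglik=ll, chain=chain,
                            node_probs=node_probs, acceptance=acceptance,
                            convergence=conv)


def stepping_stone(tree: RootedTree, tips: TipStates, spec: RateModelSpec,
                   stones: int = 100, iterations: int = 10_000,
                   seed: int = 0, burnin_frac: float = 0.2,
                   alpha: float = 0.4) -> MarginalLikelihood:
    """Stepping-stone estimate of the log marginal likelihood.

    Powers follow the Beta(alpha, 1)-quantile ladder ``beta_j = (j/K)^(1/alpha)``
    (alpha = 0.4, the usual choice, concentrating stones near the prior).
    One chain is annealed from the posterior (beta = 1) down to the prior;
    at each stone, ``iterations`` likelihood draws contribute
    ``log mean exp((beta_{j+1} - beta_j) * logL)``.
    """
    K = stones
    betas = (np.arange(K + 1) / K) ** (1.0 / alpha)
    ctx = PruningContext(tree, tips, spec.k, spec.root_prior)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sampler = _Sampler(ctx, spec, rng, beta=1.0)
    nburn = max(1, int(burnin_frac * iterations))
    # settle at the posterior first
    for _ in range(nburn * 2):
        sampler.step()
    sampler.freeze_tuning()

    stone_logw = np.empty(K)
    for j in range(K - 1, -1, -1):
        sampler.beta = betas[j]
        for _ in range(nburn):
            sampler.step()
        d = betas[j + 1] - betas[j]
        vals = np.empty(iterations)
        for i in range(iterations):
            sampler.step()
            vals[i] = sampler.ll
        w = d * vals
        mx = w.max()
        if not np.isfinite(mx):
            raise RuntimeError(
                "degenerate stepping-stone weights (all -inf); use more "
                "stones / smaller spacing")
        stone_logw[j] = mx + math.log(np.mean(np.exp(w - mx)))
    return MarginalLikelihood(logml=float(stone_logw.sum()),
                              stone_log_weights=stone_logw, betas=betas)


def evidence_label(bf: float) -> str:
    """Evidence category for a doubled-log-scale Bayes factor."""
    if bf > 20:
        return "very strong"
    if bf >= 10:
        return "strong-to-very-strong"
    if bf >= 5:
        return "strong"
    if bf > 2:
        return "positive"
    return "none"


def bayes_factor(logml_complex: float, logml_simple: float) -> tuple[float, str]:
    """BF = 2 x (log mL_complex - log mL_simple), with its evidence label."""
    if not (np.isfinite(logml_complex) and np.isfinite(logml_simple)):
        raise ValueError("marginal likelihood estimates must be finite")
    bf = 2.0 * (logml_complex - logml_simple)
    return bf, evidence_label(bf)
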