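"""Cell-wall trait encoding, correlation testing and the model x root grid.

Two traits are analysed: the membrane count (0 = one membrane/monoderm,
1 = two membranes/diderm) and the peptidoglycan layer (0 = absent, 1 = thin,
2 = thick, with ``{1,2}`` allowed as an ambiguity set for taxa whose
thickness is undocumented).

Correlated evolution between the two traits is tested the Pagel way: a
4-state chain over the joint states (00, 01, 10, 11) under an *independent*
model (each trait's rates do not depend on the other trait's state; 4 free
rates) versus a *dependent* model (8 free rates), both forbidding
simultaneous double transitions.  The three-state peptidoglycan trait is
first recoded to binary under one of three cases (A/B/C).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mcmc
from .ctmc import TipStates
from .mcmc import ChainSettings, RateModelSpec, bayes_factor, model_spec
from .tree import RootedTree, reroot, scale_branches, tag_mrca

__all__ = [
    "TraitMatrix",
    "RECODING_CASES",
    "recode_pg",
    "recode_pg_column",
    "PairModel",
    "build_independent_model",
    "build_dependent_model",
    "combine_binary_traits",
    "CorrelationResult",
    "correlation_test",
    "run_grid",
]

MEMBRANE_STATES = (0, 1)
PG_STATES = (0, 1, 2)
PG_AMBIGUOUS = frozenset({1, 2})


@dataclass
class TraitMatrix:
    """Per-taxon membrane and peptidoglycan states (with ambiguity sets)."""

    membrane: TipStates
    peptidoglycan: TipStates

    def validate(self, tree: RootedTree) -> None:
        for name, column, alphabet in (("membrane", self.membrane, {0, 1}),
                                       ("peptidoglycan", self.peptidoglycan, {0, 1, 2})):
            missing = sorted(tree.taxa - set(column))
            if missing:
                raise ValueError(f"{name}: taxa missing from table: {missing}")
            for taxon, states in column.items():
                if not frozenset(states) <= alphabet:
                    raise ValueError(f"{name}: {taxon!r} has states {set(states)} "
                                     f"outside {alphabet}")


# -- peptidoglycan recoding -------------------------------------------------

#: case -> mapping of unambiguous PG state to binary state
RECODING_CASES = {
    "A": {0: 0, 1: 1, 2: 1},   # absence vs presence (thin or thick)
    "B": {0: 0, 1: 0, 2: 1},   # thick vs the rest
    "C": {0: 0, 1: 1, 2: 0},   # thin vs the rest
}


def recode_pg(state, case: str) -> int:
    """Recode one peptidoglycan state to binary under case A, B or C.

    The ambiguity set {1,2} (undocumented thickness) is treated as *thin*
    when recoding, so it maps as state 1 does.
    """
    if case not in RECODING_CASES:
        raise ValueError(f"unknown recoding case {case!r}")
    mapping = RECODING_CASES[case]
    if isinstance(state, (set, frozenset)):
        if frozenset(state) == PG_AMBIGUOUS:
            return mapping[1]
        if len(state) == 1:
            return recode_pg(next(iter(state)), case)
        raise ValueError(f"unsupported ambiguity set {set(state)}")
    if state not in mapping:
        raise ValueError(f"peptidoglycan state {state!r} outside {{0,1,2}}")
    return mapping[state]


def recode_pg_column(pg: TipStates, case: str) -> TipStates:
    return {taxon: frozenset({recode_pg(states, case)}) for taxon, states in pg.items()}


# -- joint two-trait models ---------------------------------------------------

def pair_state(s1: int, s2: int) -> int:
    """Joint state index for (trait1, trait2) = 2*s1 + s2 (00,01,10,11)."""
    return 2 * s1 + s2


#: double transitions (both traits changing at once) are structurally forbidden
DOUBLE_CHANGES = frozenset({(0, 3), (3, 0), (1, 2), (2, 1)})


@dataclass
class PairModel:
    """Structure of a 4-state two-binary-trait chain."""

    name: str
    groups: tuple[tuple[tuple[int, int], ...], ...]
    forbidden: frozenset = DOUBLE_CHANGES

    @property
    def n_free(self) -> int:
        return len(self.groups)

    @property
    def n_structural_zeros(self) -> int:
        return len(self.forbidden)

    def spec(self, scheme: str = "H1", settings: ChainSettings | None = None,
             **kw) -> RateModelSpec:
        return model_spec(scheme, 4, forbidden=self.forbidden,
                          groups=self.groups, settings=settings, **kw)


def build_independent_model() -> PairModel:
    """4 free rates: each trait's gain/loss is tied across the other trait."""
    groups = (
        ((0, 2), (1, 3)),   # trait1 gain
        ((2, 0), (3, 1)),   # trait1 loss
        ((0, 1), (2, 3)),   # trait2 gain
        ((1, 0), (3, 2)),   # trait2 loss
    )
    return PairModel(name="independent", groups=groups)


def build_dependent_model() -> PairModel:
    """8 free single-change rates (each conditional on the other trait)."""
    groups = tuple(((i, j),) for (i, j) in
                   [(0, 1), (0, 2), (1, 0), (1, 3), (2, 0), (2, 3), (3, 1), (3, 2)])
    return PairModel(name="dependent", groups=groups)


def combine_binary_traits(t1: TipStates, t2: TipStates) -> TipStates:
    """Joint 4-state tip data; ambiguity combines as the product set."""
    if set(t1) != set(t2):
        raise ValueError("the two traits cover different taxon sets")
    out: TipStates = {}
    for taxon in t1:
        out[taxon] = frozenset(pair_state(a, b)
                               for a, b in itertools.product(t1[taxon], t2[taxon]))
    return out


# -- correlation test ----------------------------------------------------------

@dataclass
class CorrelationResult:
    bf: float
    label: str
    logml_dependent: float
    logml_independent: float
    case: str | None = None


def correlation_test(tree: RootedTree, trait1: TipStates, trait2: TipStates,
                     case: str | None = None, scheme: str = "H1",
                     stones: int = 100, iterations: int = 10_000,
                     seed: int = 0) -> CorrelationResult:
    """Dependent-vs-independent Bayes factor for two binary traits.

    If *case* is given, *trait2* is taken to be the 3-state peptidoglycan
    column and is recoded first.  Marginal likelihoods come from the
    stepping-stone sampler; BF is on the doubled-log scale.
    """
    if case is not None:
        trait2 = recode_pg_column(trait2, case)
    for name, col in (("trait1", trait1), ("trait2", trait2)):
        for taxon, states in col.items():
            if not frozenset(states) <= {0, 1}:
                raise ValueError(f"{name}: {taxon!r} is not binary after recoding")
    joint = combine_binary_traits(trait1, trait2)
    dep = build_dependent_model()
    ind = build_independent_model()
    ml_dep = mcmc.stepping_stone(tree, joint, dep.spec(scheme), stones=stones,
                                 iterations=iterations, seed=seed)
    ml_ind = mcmc.stepping_stone(tree, joint, ind.spec(scheme), stones=stones,
                                 iterations=iterations, seed=seed + 1)
    bf, label = bayes_factor(ml_dep.logml, ml_ind.logml)
    return CorrelationResult(bf=bf, label=label, logml_dependent=ml_dep.logml,
                             logml_independent=ml_ind.logml, case=case)


# -- the model x root x trait grid ---------------------------------------------

@dataclass
class GridResult:
    summaries: dict           # (trait, root, scheme) -> PosteriorSummary
    table1: pd.DataFrame      # rows node/trait/statistic, columns models
    bf_table: pd.DataFrame | None
    failures: dict = field(default_factory=dict)


def run_grid(tree: RootedTree, traits: dict[str, TipStates],
             schemes=("E", "H1", "H2", "R1", "R2"),
             roots: dict[str, frozenset] | None = None,
             tags: dict[str, frozenset] | None = None,
             settings: ChainSettings | None = None,
             scale_mean: float = 0.1, ks: dict[str, int] | None = None,
             bf_stones: int = 0, bf_iterations: int = 0,
             bf_root: str | None = None, seed: int = 0) -> GridResult:
    """Run every (trait, root, model) combination and tabulate the results.

    ``roots`` maps a root name to an outgroup taxon set (``None`` entry =
    keep the tree as given); ``tags`` maps ancestor names to taxon sets
    (re-resolved after each rerooting).  The summary table has one row per
    (node, trait, statistic) with the mean q_ij rates first, then the mean
    ancestral state probabilities P(i) (in percent), one column per model.
    If ``bf_stones`` > 0, pairwise Bayes factors between models are computed
    by stepping stone on ``bf_root`` (default: the first root).
    """
    roots = roots or {"as-given": None}
    tags = tags or {}
    settings = settings or ChainSettings()
    summaries: dict = {}
    failures: dict = {}
    logml: dict = {}
    bf_root = bf_root if bf_root is not None else next(iter(roots))

    for root_name, outgroup in roots.items():
        t = tree if outgroup is None else reroot(tree, outgroup)
        t = scale_branches(t, scale_mean) if scale_mean else t
        t = tag_mrca(t, "LBCA", sorted(t.taxa))
        for tag_name, taxa in tags.items():
            t = tag_mrca(t, tag_name, taxa)
        tag_names = ("LBCA",) + tuple(tags)
        for trait_name, tips in traits.items():
            k = ks.get(trait_name) if ks else None
            if k is None:
                k = max(2, max(max(s) for s in tips.values()) + 1)
            for si, scheme in enumerate(schemes):
                key = (trait_name, root_name, scheme)
                spec = model_spec(scheme, k, settings=settings)
                digest = zlib.crc32("|".join(key).encode())
                cell_seed = (seed + digest) % 2**31
                try:
                    summaries[key] = mcmc.sample_posterior(
                        t, tips, spec, tags=tag_names,
                        settings=ChainSettings(
                            iterations=settings.iterations, burnin=settings.burnin,
                            thinning=settings.thinning, n_chains=settings.n_chains,
                            seed=cell_seed))
                    if bf_stones and root_name == bf_root:
                        ml = mcmc.stepping_stone(
                            t, tips, spec, stones=bf_stones,
                            iterations=bf_iterations or 1000, seed=cell_seed + 1)
                        logml[(trait_name, scheme)] = ml.logml
                except Exception as exc:  # keep the grid going
                    failures[key] = repr(exc)

    table1 = _table1(summaries, schemes)
    bf_table = _bf_table(logml, traits, schemes) if logml else None
    return GridResult(summaries=summaries, table1=table1, bf_table=bf_table,
                      failures=failures)


def _table1(summaries: dict, schemes) -> pd.DataFrame:
    rows: dict[tuple, dict] = {}
    for (trait, root, scheme), summ in summaries.items():
        for pair in summ.pairs:
            key = (root, "LBCA", trait, f"mean q{pair[0]}{pair[1]}")
            rows.setdefault(key, {})[scheme] = summ.rate_mean(pair)
        for tag, probs in summ.node_probs.items():
            mean = probs.mean(axis=0)
            for s, p in enumerate(mean):
                key = (root, tag, trait, f"mean P({s})")
                rows.setdefault(key, {})[scheme] = 100.0 * p
    index = pd.MultiIndex.from_tuples(sorted(rows),
                                      names=["root", "node", "trait", "statistic"])
    return pd.DataFrame([rows[k] for k in sorted(rows)], index=index,
                        columns=list(schemes))


def _bf_table(logml: dict, traits, schemes) -> pd.DataFrame:
    recs = []
    order = {s: i for i, s in enumerate(schemes)}
    for a, b in itertools.combinations(schemes, 2):
        for trait in traits:
            if (trait, a) in logml and (trait, b) in logml:
                # "complex" = the better-fitting of the pair, as in a pairwise
                # model-comparison table
                bf, label = bayes_factor(logml[(trait, a)], logml[(trait, b)])
                recs.append({"complex": a, "simple": b, "trait": trait,
                             "BF": bf, "evidence": label})
    return pd.DataFrame(recs)
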