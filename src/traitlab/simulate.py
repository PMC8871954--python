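"""Synthetic inputs with the statistical structure the analyses assume.

Everything here is a pure function of its configuration and seed: Yule
(pure-birth) trees rescaled to the working mean branch length of 0.1,
discrete traits evolved by exact CTMC jump-chain simulation, jointly
evolving correlated binary trait pairs, dcw gene orders evolving by gene
escape/loss (no gain, matching the locus's inferred history), and
phylum-structured presence/absence matrices with flip noise.

Default truth rates for the binary trait (gain 2.4, loss 0.1) sit at the
magnitude inferred for the membrane trait, so recovery experiments probe the
regime the real analysis operates in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import RateMatrix
from .patterns import OM_GENES, PATTERN_TRUTHS
from .synteny import DCW_FAMILIES, EncodedKaryotype, karyotype_adjacencies
from .tree import RootedTree, scale_branches

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_trait",
    "simulate_dependent_pair",
    "simulate_gene_orders",
    "simulate_presence_matrix",
    "DEFAULT_TRUTH_Q",
]

#: binary-trait truth rates of the magnitude inferred for the membrane trait
DEFAULT_TRUTH_Q = RateMatrix(k=2, rates={(0, 1): 2.4, (1, 0): 0.1})


@dataclass
class SimulationConfig:
    seed: int
    n_tips: int = 85
    birth_rate: float = 1.0
    mean_branch_length: float = 0.1
    q_truth: RateMatrix = field(default_factory=lambda: DEFAULT_TRUTH_Q)
    p_escape: float = 0.02
    p_loss: float = 0.02
    pattern_noise: float = 0.05

    def __post_init__(self):
        for p in (self.p_escape, self.p_loss, self.pattern_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("event probabilities must lie in [0,1]")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is mandatory for synthetic data")
    return np.random.default_rng(seed)


# -- trees ---------------------------------------------------------------------

def simulate_tree(n_tips: int | None = None, seed=None, birth_rate: float = 1.0,
                  duration: float | None = None,
                  mean_branch_length: float | None = 0.1) -> RootedTree:
    """A Yule (pure-birth) tree, grown either to *n_tips* or for *duration*.

    Lineages split independently at rate *birth_rate*; the resulting tree is
    ultrametric.  Unless ``mean_branch_length`` is None, branch lengths are
    rescaled to the requested mean (0.1, the working scale for rate
    inference).
    """
    if (n_tips is None) == (duration is None):
        raise ValueError("specify exactly one of n_tips or duration")
    if n_tips is not None and n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _rng(seed)

    parent_map: dict[int, int] = {}
    birth: dict[int, float] = {}
    next_id = 0

    root = next_id; next_id += 1
    birth[root] = 0.0
    active = []
    for _ in range(2):
        birth[next_id] = 0.0
        parent_map[next_id] = root
        active.append(next_id)
        next_id += 1
    t = 0.0
    while True:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        if duration is not None and t + wait > duration:
            t = duration
            break
        t += wait
        if n_tips is not None and len(active) == n_tips:
            break
        victim = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            birth[next_id] = t
            parent_map[next_id] = victim
            active.append(next_id)
            next_id += 1
    death = {v: t for v in active}  # extend all extant lineages to the present

    n = next_id
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    tip_labels: dict[int, str] = {}
    for v, p in parent_map.items():
        parent[v] = p
        children[p].append(v)
    for v in parent_map:
        end = death[v] if v in death else birth[children[v][0]]
        blen[v] = end - birth[v]
    for i, v in enumerate(sorted(active)):
        tip_labels[v] = f"t{i + 1}"
    tree = RootedTree(parent=parent, children=children, blen=blen,
                      tip_labels=tip_labels)
    tree.validate()
    if mean_branch_length is not None:
        tree = scale_branches(tree, mean_branch_length)
    return tree


# -- traits --------------------------------------------------------------------

def _evolve_branch(state: int, t: float, Q: np.ndarray,
                   rng: np.random.Generator, events: list | None = None) -> int:
    """Exact jump-chain simulation of a CTMC along one branch."""
    k = Q.shape[0]
    remaining = t
    while True:
        rate_out = -Q[state, state]
        if rate_out <= 0.0:
            return state
        wait = rng.exponential(1.0 / rate_out)
        if wait >= remaining:
            return state
        remaining -= wait
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        new = int(rng.choice(k, p=probs))
        if events is not None:
            events.append((state, new))
        state = new


def simulate_trait(tree: RootedTree, Q: RateMatrix | np.ndarray, seed=None,
                   root_state: int | None = None):
    """Evolve one discrete trait down the tree.

    Returns ``(tips, node_states)``: per-taxon singleton state sets (ready
    for the likelihood machinery) and the full true node states, including
    ancestors, for recovery scoring.
    """
    rng = _rng(seed)
    A = Q.matrix() if isinstance(Q, RateMatrix) else np.asarray(Q, float)
    k = A.shape[0]
    states: dict[int, int] = {}
    for v in tree.preorder():
        if tree.parent[v] < 0:
            states[v] = (int(rng.integers(k)) if root_state is None
                         else int(root_state))
        else:
            states[v] = _evolve_branch(states[int(tree.parent[v])],
                                       float(tree.blen[v]), A, rng)
    tips = {tree.tip_labels[v]: frozenset({states[v]}) for v in tree.tips()}
    return tips, states


def simulate_dependent_pair(tree: RootedTree, Q4: RateMatrix | np.ndarray,
                            seed=None, root_state: int = 0):
    """Evolve a correlated pair of binary traits jointly on the 4-state chain.

    The generator must have the double-change rates (00<->11, 01<->10) at
    zero.  Returns ``(trait1, trait2, events)`` where the event log lists
    every (from, to) jump that occurred.
    """
    rng = _rng(seed)
    A = Q4.matrix() if isinstance(Q4, RateMatrix) else np.asarray(Q4, float)
    if A.shape != (4, 4):
        raise ValueError("need a 4-state joint generator")
    for i, j in ((0, 3), (3, 0), (1, 2), (2, 1)):
        if A[i, j] != 0.0:
            raise ValueError("double-change rates must be structurally zero")
    events: list = []
    states: dict[int, int] = {}
    for v in tree.preorder():
        if tree.parent[v] < 0:
            states[v] = int(root_state)
        else:
            states[v] = _evolve_branch(states[int(tree.parent[v])],
                                       float(tree.blen[v]), A, rng, events)
    t1 = {tree.tip_labels[v]: frozenset({states[v] // 2}) for v in tree.tips()}
    t2 = {tree.tip_labels[v]: frozenset({states[v] % 2}) for v in tree.tips()}
    return t1, t2, events


def dependent_truth(strength: float = 40.0, base: float = 1.0) -> RateMatrix:
    """A strongly dependent 8-rate truth: trait2 turns on/off *strength*
    times faster when trait1 is on, and vice versa."""
    hi = base * np.sqrt(strength)
    lo = base / np.sqrt(strength)
    rates = {
        (0, 1): lo, (1, 0): hi,    # trait2 while trait1 = 0
        (2, 3): hi, (3, 2): lo,    # trait2 while trait1 = 1
        (0, 2): lo, (2, 0): hi,    # trait1 while trait2 = 0
        (1, 3): hi, (3, 1): lo,    # trait1 while trait2 = 1
    }
    return RateMatrix(k=4, rates=rates,
                      forbidden=frozenset({(0, 3), (3, 0), (1, 2), (2, 1)}))


def independent_truth(gain1=1.0, loss1=1.0, gain2=1.0, loss2=1.0) -> RateMatrix:
    rates = {
        (0, 2): gain1, (1, 3): gain1, (2, 0): loss1, (3, 1): loss1,
        (0, 1): gain2, (2, 3): gain2, (1, 0): loss2, (3, 2): loss2,
    }
    return RateMatrix(k=4, rates=rates,
                      forbidden=frozenset({(0, 3), (3, 0), (1, 2), (2, 1)}))


# -- gene orders -----------------------------------------------------------------

def _ancestral_karyotype(name: str) -> EncodedKaryotype:
    return EncodedKaryotype(genome=name,
                            chromosomes=[[(f, 1) for f in DCW_FAMILIES]])


def simulate_gene_orders(tree: RootedTree, p_escape: float = 0.02,
                         p_loss: float = 0.02, seed=None,
                         ancestral: EncodedKaryotype | None = None):
    """Evolve dcw gene orders by per-branch gene escape and loss (no gain).

    Each gene independently, per branch: with probability *p_loss* it is
    lost from the genome; otherwise with probability *p_escape* it escapes
    the cluster onto its own new molecule.  Returns ``(table, karyotypes,
    true_adjacencies)`` with the extant gene-order table (TSV-ready
    DataFrame), the true karyotype at every node, and the true adjacency set
    at every node for recovery scoring.
    """
    rng = _rng(seed)
    kars: dict[int, EncodedKaryotype] = {}
    for v in tree.preorder():
        if tree.parent[v] < 0:
            kars[v] = ancestral or _ancestral_karyotype("root")
            continue
        parent_kar = kars[int(tree.parent[v])]
        chroms = [list(c) for c in parent_kar.chromosomes]
        escaped: list[tuple[str, int]] = []
        new_chroms: list[list[tuple[str, int]]] = []
        for chrom in chroms:
            kept: list[tuple[str, int]] = []
            for gene in chrom:
                u = rng.random()
                if u < p_loss:
                    continue
                if u < p_loss + p_escape:
                    escaped.append(gene)
                else:
                    kept.append(gene)
            if kept:
                new_chroms.append(kept)
        new_chroms.extend([g] for g in escaped)
        name = tree.tip_labels.get(v, f"node{v}")
        kars[v] = EncodedKaryotype(genome=name, chromosomes=new_chroms)

    rows = []
    for v in tree.tips():
        kar = kars[v]
        for ci, chrom in enumerate(kar.chromosomes):
            molecule = f"chr{ci + 1}"
            for gi, (fam, strand) in enumerate(chrom):
                rows.append({"genome": kar.genome, "molecule": molecule,
                             "index": gi + 1, "strand": "+" if strand == 1 else "-",
                             "family": fam, "start": 1000 * (gi + 1),
                             "molecule_size": len(chrom)})
    table = pd.DataFrame(rows, columns=["genome", "molecule", "index",
                                        "strand", "family", "start",
                                        "molecule_size"])
    true_adjs = {v: karyotype_adjacencies(k) for v, k in kars.items()}
    return table, kars, true_adjs


# -- presence/absence matrices ----------------------------------------------------

def simulate_presence_matrix(phylum_patterns: dict[str, int] | None = None,
                             genomes_per_phylum: int = 12,
                             noise: float = 0.05, seed=None):
    """Phylum-structured genome x gene boolean matrix with flip noise.

    ``phylum_patterns`` maps phylum name to generating pattern id (default:
    three phyla per pattern).  Each genome's gene vector is its phylum's
    truth vector with independent flips at probability *noise*.  Returns
    ``(matrix, phylum_map, truth)``.
    """
    if not 0.0 <= noise < 0.5:
        raise ValueError("noise must lie in [0, 0.5)")
    rng = _rng(seed)
    if phylum_patterns is None:
        phylum_patterns = {f"phylum_p{pid}_{i}": pid
                           for pid in (1, 2, 3, 4) for i in range(3)}
    rows, phylum_map = {}, {}
    for phylum, pid in sorted(phylum_patterns.items()):
        truth = np.array([PATTERN_TRUTHS[pid][g] for g in OM_GENES], dtype=bool)
        for g in range(genomes_per_phylum):
            name = f"{phylum}_g{g + 1}"
            flips = rng.random(len(OM_GENES)) < noise
            rows[name] = truth ^ flips
            phylum_map[name] = phylum
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(OM_GENES))
    return matrix, phylum_map, dict(sorted(phylum_patterns.items()))
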