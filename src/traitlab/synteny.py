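"""Gene order of the dcw (division and cell-wall synthesis) cluster.

Encodes extant gene orders into "karyotypes" (artificial chromosomes created
by telomere insertion where dcw genes are too far apart), resolves paralogs
by the cluster-context / main-molecule / orientation rule cascade, classifies
each gene family as main-cluster / sub-cluster / outside / absent, and
reconstructs ancestral adjacencies on a rooted species tree by per-adjacency
parsimony (unit-cost Sankoff with a loss-leaning resolution of ties, since
the locus's history is dominated by gene loss and delocalization rather than
gain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import RootedTree

__all__ = [
    "DCW_FAMILIES",
    "EncodedKaryotype",
    "encode_karyotype",
    "select_paralog",
    "classify_status",
    "karyotype_adjacencies",
    "fitch_state_sets",
    "reconstruct_ancestral_adjacencies",
    "AncestralSynteny",
    "read_gene_order_table",
    "write_procars_input",
]

#: the 17 families of the longest form of the cluster, in canonical order
DCW_FAMILIES = (
    "mraZ", "mraW", "ftsL", "ftsI", "murE", "murF", "mraY", "murD", "ftsW",
    "murG", "murC", "ddlB", "ftsQ", "ftsA", "ftsZ", "murA", "murB",
)

REQUIRED_COLUMNS = ("genome", "molecule", "index", "strand", "family")


def read_gene_order_table(path) -> pd.DataFrame:
    """Read a gene-order TSV: genome, molecule, index, strand, family
    (+ optional start, molecule_size).  ``index`` is the ordinal position of
    the gene among *all* genes on its molecule, so index gaps measure the
    number of intervening non-dcw genes."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene-order table missing columns: {missing}")
    return df


@dataclass
class EncodedKaryotype:
    """One genome's dcw genes as signed, ordered artificial chromosomes."""

    genome: str
    chromosomes: list[list[tuple[str, int]]]   # [(family, strand +1/-1), ...]
    telomere_log: list = field(default_factory=list)
    paralog_log: list = field(default_factory=list)

    def families(self) -> set[str]:
        return {fam for chrom in self.chromosomes for fam, _ in chrom}

    def validate(self) -> None:
        seen: list[str] = [f for chrom in self.chromosomes for f, _ in chrom]
        if len(seen) != len(set(seen)):
            dup = sorted({f for f in seen if seen.count(f) > 1})
            raise ValueError(f"{self.genome}: families appear twice: {dup}")


def _strand_int(s) -> int:
    if s in (1, -1):
        return int(s)
    if s in ("+", "1"):
        return 1
    if s in ("-", "-1"):
        return -1
    raise ValueError(f"bad strand {s!r}")


def select_paralog(copies: list[dict], chrom_family_counts: dict[int, int],
                   main_molecule: str, main_strand: int) -> tuple[int, str]:
    """Pick one copy of a duplicated family.  Returns (index into *copies*, rule).

    Rules, in order: (1) the copy on the artificial chromosome carrying the
    most *other* dcw genes; (2) the copy on the main DNA molecule (genuine
    chromosome / largest scaffold); (3) the copy in the same orientation as
    the dcw genes of the main molecule; (4) the copy with the lowest
    coordinate (deterministic last resort).
    """
    scores = [chrom_family_counts[c["chrom"]] for c in copies]
    best = max(scores)
    tied = [i for i, s in enumerate(scores) if s == best]
    if len(tied) == 1:
        return tied[0], "cluster-context"
    on_main = [i for i in tied if copies[i]["molecule"] == main_molecule]
    if len(on_main) == 1:
        return on_main[0], "main-molecule"
    if on_main:
        tied = on_main
    oriented = [i for i in tied if copies[i]["strand"] == main_strand]
    if len(oriented) == 1:
        return oriented[0], "orientation"
    if oriented:
        tied = oriented
    tied.sort(key=lambda i: copies[i]["pos"])
    return tied[0], "lowest-coordinate"


def encode_karyotype(genome_df: pd.DataFrame, gap_threshold: float = 5,
                     mode: str = "genes") -> EncodedKaryotype:
    """Encode one genome's dcw gene order with artificial telomeres.

    Consecutive dcw genes on the same molecule separated by more than
    *gap_threshold* intervening non-dcw genes (``mode="genes"``, using the
    ``index`` column) or by more than *gap_threshold* bases
    (``mode="kb"``, using ``start``) are split onto distinct artificial
    chromosomes.  Tandem copies of a family collapse to a single gene; any
    remaining paralogs are resolved by :func:`select_paralog`.
    """
    genome = str(genome_df["genome"].iloc[0])
    coord_col = "index" if mode == "genes" else "start"
    if mode not in ("genes", "kb"):
        raise ValueError("mode must be 'genes' or 'kb'")

    chroms: list[list[dict]] = []
    telomere_log: list = []
    for molecule, sub in genome_df.groupby("molecule", sort=True):
        sub = sub.sort_values(coord_col)
        current: list[dict] = []
        prev_coord = None
        for _, row in sub.iterrows():
            entry = {"family": row["family"], "strand": _strand_int(row["strand"]),
                     "molecule": str(molecule), "pos": float(row[coord_col])}
            if prev_coord is not None:
                gap = (row[coord_col] - prev_coord - 1 if mode == "genes"
                       else row[coord_col] - prev_coord)
                if gap > gap_threshold:
                    telomere_log.append((genome, str(molecule), float(gap)))
                    chroms.append(current)
                    current = []
            current.append(entry)
            prev_coord = row[coord_col]
        if current:
            chroms.append(current)

    # collapse tandem duplicates (adjacent same-family copies)
    for chrom in chroms:
        i = 1
        while i < len(chrom):
            if chrom[i]["family"] == chrom[i - 1]["family"]:
                del chrom[i]
            else:
                i += 1

    # paralog resolution
    paralog_log: list = []
    if "molecule_size" in genome_df.columns:
        main_molecule = str(genome_df.loc[genome_df["molecule_size"].idxmax(), "molecule"])
    else:
        main_molecule = str(min(genome_df["molecule"].astype(str)))
    main_strands = [g["strand"] for ch in chroms for g in ch
                    if g["molecule"] == main_molecule]
    main_strand = 1 if not main_strands else (1 if np.mean(main_strands) >= 0 else -1)

    positions: dict[str, list[dict]] = {}
    for ci, chrom in enumerate(chroms):
        for gi, g in enumerate(chrom):
            positions.setdefault(g["family"], []).append(
                {**g, "chrom": ci, "offset": gi})
    drop: set[tuple[int, int]] = set()
    for family, copies in positions.items():
        if len(copies) <= 1:
            continue
        counts = {}
        for c in copies:
            counts[c["chrom"]] = sum(1 for g in chroms[c["chrom"]]
                                     if g["family"] != family)
        chosen, rule = select_paralog(copies, counts, main_molecule, main_strand)
        paralog_log.append((genome, family, rule))
        for i, c in enumerate(copies):
            if i != chosen:
                drop.add((c["chrom"], c["offset"]))

    out_chroms = []
    for ci, chrom in enumerate(chroms):
        kept = [(g["family"], g["strand"]) for gi, g in enumerate(chrom)
                if (ci, gi) not in drop]
        if kept:
            out_chroms.append(kept)
    kar = EncodedKaryotype(genome=genome, chromosomes=out_chroms,
                           telomere_log=telomere_log, paralog_log=paralog_log)
    kar.validate()
    return kar


def classify_status(karyotype: EncodedKaryotype,
                    families=DCW_FAMILIES) -> dict[str, str]:
    """Cluster status per family: main-cluster / sub-cluster / outside / absent.

    The main cluster is the largest dcw-carrying chromosome provided it has
    at least 3 genes (ties are reported as ``main-cluster(tied)``); other
    chromosomes with >= 2 genes are sub-clusters; singletons are outside.
    """
    sizes = [len(c) for c in karyotype.chromosomes]
    status: dict[str, str] = {f: "absent" for f in families}
    main_ids: set[int] = set()
    if sizes:
        biggest = max(sizes)
        if biggest >= 3:
            main_ids = {i for i, s in enumerate(sizes) if s == biggest}
    tied = len(main_ids) > 1
    for ci, chrom in enumerate(karyotype.chromosomes):
        if ci in main_ids:
            label = "main-cluster(tied)" if tied else "main-cluster"
        elif len(chrom) >= 2:
            label = "sub-cluster"
        else:
            label = "outside"
        for fam, _ in chrom:
            status[fam] = label
    return status


# -- adjacencies ---------------------------------------------------------------

def _ends(family: str, strand: int) -> tuple[tuple[str, str], tuple[str, str]]:
    """(left extremity, right extremity) of an oriented gene."""
    head, tail = (family, "h"), (family, "t")
    return (tail, head) if strand == 1 else (head, tail)


def karyotype_adjacencies(karyotype: EncodedKaryotype) -> frozenset:
    """Unordered signed adjacencies between gene extremities."""
    adjs = set()
    for chrom in karyotype.chromosomes:
        for (f1, s1), (f2, s2) in zip(chrom, chrom[1:]):
            _, right = _ends(f1, s1)
            left, _ = _ends(f2, s2)
            adjs.add(frozenset((right, left)))
    return frozenset(adjs)


def fitch_state_sets(tree: RootedTree, tip_states: dict[str, int]) -> dict[int, frozenset]:
    """Per-node sets of states attainable in some minimum-change labeling.

    Unit-cost Sankoff up and down passes for a binary presence/absence
    character; the returned set at node v is argmin over states of the total
    tree cost when v is pinned (the MPR state set).
    """
    n = tree.n_nodes
    INF = 10 ** 9
    below = np.zeros((n, 2))
    for v in tree.postorder():
        if tree.is_tip(v):
            s = tip_states[tree.tip_labels[v]]
            below[v] = [0 if s == 0 else INF, 0 if s == 1 else INF]
        else:
            for c in tree.children[v]:
                below[v, 0] += min(below[c, 0], below[c, 1] + 1)
                below[v, 1] += min(below[c, 1], below[c, 0] + 1)
    above = np.zeros((n, 2))
    for u in tree.preorder():
        for v in tree.children[u]:
            sib = np.zeros(2)
            for w in tree.children[u]:
                if w != v:
                    sib[0] += min(below[w, 0], below[w, 1] + 1)
                    sib[1] += min(below[w, 1], below[w, 0] + 1)
            base = above[u] + sib
            above[v, 0] = min(base[0], base[1] + 1)
            above[v, 1] = min(base[1], base[0] + 1)
    out: dict[int, frozenset] = {}
    for v in range(n):
        tot = below[v] + above[v]
        out[v] = frozenset(np.flatnonzero(tot == tot.min()).tolist())
    return out


@dataclass
class AncestralSynteny:
    """Ancestral adjacency calls and per-node cluster status."""

    adjacencies: dict[int, frozenset]          # node -> adjacency set
    karyotypes: dict[int, EncodedKaryotype]    # node -> assembled gene order
    status: pd.DataFrame                       # node x family status table
    mpr_sets: dict                             # adjacency -> node -> state set
    conflicts: list = field(default_factory=list)


def _assemble_chromosomes(adjs: set, families: set[str]) -> list[list[tuple[str, int]]]:
    """Greedy walk of the adjacency graph into signed linear gene orders."""
    neighbour: dict[tuple[str, str], tuple[str, str]] = {}
    for adj in adjs:
        a, b = tuple(adj)
        neighbour[a] = b
        neighbour[b] = a
    seen: set[str] = set()
    chroms: list[list[tuple[str, int]]] = []
    # start walks at free extremities so linear chromosomes are complete
    ends = [e for fam in sorted(families) for e in ((fam, "t"), (fam, "h"))]
    starts = [e for e in ends if e not in neighbour] + ends
    for start in starts:
        fam = start[0]
        if fam in seen:
            continue
        chrom: list[tuple[str, int]] = []
        ext = start
        while ext[0] not in seen:
            fam = ext[0]
            seen.add(fam)
            strand = 1 if ext[1] == "t" else -1  # entered at tail -> forward
            chrom.append((fam, strand))
            other = (fam, "h" if ext[1] == "t" else "t")
            if other not in neighbour:
                break
            ext = neighbour[other]
        chroms.append(chrom)
    return chroms


def reconstruct_ancestral_adjacencies(tree: RootedTree,
                                      karyotypes: dict[str, EncodedKaryotype],
                                      families=DCW_FAMILIES) -> AncestralSynteny:
    """Per-adjacency parsimony reconstruction of ancestral gene orders.

    Every adjacency observed in any extant genome becomes a binary character;
    MPR state sets are computed per node; ambiguous nodes resolve toward
    presence (loss-leaning).  Accepted adjacencies are made consistent (one
    adjacency per gene extremity) by dropping the lower-leaf-support side of
    any conflict, then assembled into linear orders.  A family missing from
    all adjacencies of a node is still emitted, as "outside" (ancestors are
    never called absent).
    """
    missing = sorted(tree.taxa - set(karyotypes))
    if missing:
        raise ValueError(f"tips without karyotypes: {missing}")
    tip_adjs = {taxon: karyotype_adjacencies(kar)
                for taxon, kar in karyotypes.items()}
    all_adjs = sorted({a for s in tip_adjs.values() for a in s},
                      key=lambda a: sorted(map(str, a)))
    support = {a: sum(1 for s in tip_adjs.values() if a in s) for a in all_adjs}

    mpr: dict = {}
    calls: dict[int, set] = {v: set() for v in range(tree.n_nodes)}
    for adj in all_adjs:
        states = {taxon: int(adj in s) for taxon, s in tip_adjs.items()}
        sets = fitch_state_sets(tree, states)
        mpr[adj] = sets
        for v in range(tree.n_nodes):
            if not tree.is_tip(v) and 1 in sets[v]:  # presence-leaning tie-break
                calls[v].add(adj)
    for v in tree.tips():
        calls[v] = set(tip_adjs[tree.tip_labels[v]])

    conflicts: list = []
    out_adj: dict[int, frozenset] = {}
    out_kar: dict[int, EncodedKaryotype] = {}
    status_rows = {}
    present_fams = {f for kar in karyotypes.values() for f in kar.families()}
    for v in range(tree.n_nodes):
        accepted: dict[tuple[str, str], frozenset] = {}
        kept: set = set()
        for adj in sorted(calls[v], key=lambda a: (-support[a], sorted(map(str, a)))):
            exts = tuple(adj)
            if any(e in accepted for e in exts):
                conflicts.append((v, adj))
                continue
            for e in exts:
                accepted[e] = adj
            kept.add(adj)
        kept = _break_cycles(kept, support, conflicts, v)
        out_adj[v] = frozenset(kept)
        chroms = _assemble_chromosomes(kept, present_fams)
        name = tree.tip_labels.get(v, f"node{v}")
        kar = EncodedKaryotype(genome=name, chromosomes=chroms)
        out_kar[v] = kar
        status_rows[v] = classify_status(kar, families)

    status = pd.DataFrame.from_dict(status_rows, orient="index")
    status = status.reindex(columns=list(families))
    return AncestralSynteny(adjacencies=out_adj, karyotypes=out_kar,
                            status=status, mpr_sets=mpr, conflicts=conflicts)


def _break_cycles(adjs: set, support: dict, conflicts: list, node: int) -> set:
    """Drop the weakest adjacency of any circular component (orders are linear)."""
    adjs = set(adjs)
    while True:
        neighbour: dict = {}
        for adj in adjs:
            a, b = tuple(adj)
            neighbour.setdefault(a[0], set()).add(adj)
            neighbour.setdefault(b[0], set()).add(adj)
        # a cycle exists iff some connected component has as many adjacencies
        # as genes; find components over families
        fams = sorted(neighbour)
        seen: set = set()
        cycle_adj = None
        for f in fams:
            if f in seen:
                continue
            comp, stack, comp_adjs = set(), [f], set()
            while stack:
                g = stack.pop()
                if g in comp:
                    continue
                comp.add(g)
                for adj in neighbour.get(g, ()):
                    comp_adjs.add(adj)
                    for (fam, _end) in adj:
                        if fam not in comp:
                            stack.append(fam)
            seen |= comp
            if len(comp_adjs) >= len(comp):  # circular
                cycle_adj = min(comp_adjs,
                                key=lambda a: (support[a], sorted(map(str, a))))
                break
        if cycle_adj is None:
            return adjs
        adjs.discard(cycle_adj)
        conflicts.append((node, cycle_adj))


def write_procars_input(karyotypes: dict[str, EncodedKaryotype], path) -> None:
    """Export block files in the GRIMM-like genome format ProCARs reads."""
    with open(path, "w") as fh:
        for name in sorted(karyotypes):
            fh.write(f">{name}\n")
            for chrom in karyotypes[name].chromosomes:
                genes = " ".join(("" if s == 1 else "-") + f for f, s in chrom)
                fh.write(f"{genes} $\n")
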