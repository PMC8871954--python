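"""Rooted phylogenies: Newick I/O, rerooting, branch scaling, MRCA tagging.

The container is a flat array/dict structure (integer node ids, parent map,
children lists) sized for trees of tens to hundreds of tips, which is the
regime of phylum-level bacterial phylogenomics.  Newick parsing is delegated
to dendropy; writing uses a small serializer so read->write->read round-trips
are exact to float precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "RootedTree",
    "TreeError",
    "read_newick",
    "write_newick",
    "reroot",
    "scale_branches",
    "tag_mrca",
]

#: branch length substituted for exactly-zero internal branches before
#: likelihood work (transition matrices at t=0 make marginal reconstruction
#: at the child node degenerate with its parent)
ZERO_BRANCH_EPSILON = 1e-8


class TreeError(ValueError):
    """Raised for malformed trees, bad outgroups or unknown taxa."""


@dataclass
class RootedTree:
    """A rooted tree with branch lengths and named-ancestor tags.

    Attributes
    ----------
    parent:
        ``parent[v]`` is the parent node id of ``v``; ``-1`` for the root.
    children:
        ``children[v]`` lists the child ids of ``v`` (empty for tips).
    blen:
        ``blen[v]`` is the length of the branch *above* ``v`` (expected
        substitutions/site); 0.0 for the root.
    tip_labels:
        map node id -> taxon name for tips.
    node_tags:
        map tag name -> node id (e.g. ``"LBCA"`` -> root).
    """

    parent: np.ndarray
    children: list[list[int]]
    blen: np.ndarray
    tip_labels: dict[int, str]
    node_tags: dict[str, int] = field(default_factory=dict)

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree has {len(roots)} roots, expected exactly 1")
        return int(roots[0])

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.tip_labels.values())

    def tips(self) -> list[int]:
        return sorted(self.tip_labels)

    def node_of(self, taxon: str) -> int:
        for v, name in self.tip_labels.items():
            if name == taxon:
                return v
        raise TreeError(f"unknown taxon {taxon!r}")

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    def postorder(self) -> list[int]:
        """Node ids, children before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def path_to_root(self, v: int) -> list[int]:
        path = [v]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def mrca(self, taxa) -> int:
        """Most recent common ancestor of a set of taxon names."""
        taxa = list(taxa)
        if not taxa:
            raise TreeError("empty taxon set has no MRCA")
        paths = [set(self.path_to_root(self.node_of(t))) for t in taxa]
        common = set.intersection(*paths)
        # the common ancestor farthest from the root == deepest on any path
        for node in self.path_to_root(self.node_of(taxa[0])):
            if node in common:
                return node
        raise TreeError("disconnected tree")  # pragma: no cover

    def tipset_below(self) -> dict[int, frozenset[str]]:
        below: dict[int, frozenset[str]] = {}
        for v in self.postorder():
            if self.is_tip(v):
                below[v] = frozenset([self.tip_labels[v]])
            else:
                acc: frozenset[str] = frozenset()
                for c in self.children[v]:
                    acc |= below[c]
                below[v] = acc
        return below

    def total_branch_length(self) -> float:
        return float(self.blen.sum())

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each as its smaller/canonical side."""
        all_taxa = self.taxa
        out: set[frozenset[str]] = set()
        below = self.tipset_below()
        for v in range(self.n_nodes):
            if self.parent[v] < 0:
                continue
            side = below[v]
            other = all_taxa - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def copy(self) -> "RootedTree":
        return RootedTree(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            blen=self.blen.copy(),
            tip_labels=dict(self.tip_labels),
            node_tags=dict(self.node_tags),
        )

    def validate(self) -> None:
        labels = list(self.tip_labels.values())
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        r = self.root  # raises unless unique
        if self.blen[r] != 0.0:
            raise TreeError("root branch length must be 0")
        if np.any(np.delete(self.blen, r) < 0):
            raise TreeError("negative branch length")
        seen = self.postorder()
        if len(seen) != self.n_nodes or len(set(seen)) != self.n_nodes:
            raise TreeError("tree is not connected/acyclic")


# -- Newick I/O ----------------------------------------------------------

def read_newick(text: str) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Quoted labels and bracket comments are accepted (and comments dropped);
    polytomies, including a trifurcating unrooted-style base, are kept as-is
    until :func:`reroot` is called.  Missing branch lengths default to 0.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy reports line/column in the message
        raise TreeError(f"Newick parse error: {exc}") from exc

    ids: dict[object, int] = {}
    order = list(dt.preorder_node_iter())
    for i, nd in enumerate(order):
        ids[nd] = i
    n = len(order)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n, dtype=float)
    children: list[list[int]] = [[] for _ in range(n)]
    tip_labels: dict[int, str] = {}
    for nd in order:
        v = ids[nd]
        if nd.parent_node is not None:
            parent[v] = ids[nd.parent_node]
            children[ids[nd.parent_node]].append(v)
            blen[v] = float(nd.edge.length or 0.0)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("tip without a label")
            tip_labels[v] = nd.taxon.label
    tree = RootedTree(parent=parent, children=children, blen=blen,
                      tip_labels=tip_labels)
    tree.validate()
    return tree


def _needs_quoting(label: str) -> bool:
    special = set(" ()[]':;,")
    return any(ch in special for ch in label)


def write_newick(tree: RootedTree) -> str:
    """Serialize to Newick with full float precision."""

    def fmt(v: int) -> str:
        if tree.is_tip(v):
            label = tree.tip_labels[v]
            if _needs_quoting(label):
                label = "'" + label.replace("'", "''") + "'"
            body = label
        else:
            body = "(" + ",".join(fmt(c) for c in tree.children[v]) + ")"
        if tree.parent[v] < 0:
            return body
        return f"{body}:{tree.blen[v]:.17g}"

    return fmt(tree.root) + ";"


# -- rerooting -----------------------------------------------------------

def reroot(tree: RootedTree, outgroup) -> RootedTree:
    """Reroot so the root separates *outgroup* from the remaining taxa.

    The outgroup must form a clade on some edge of the *unrooted* topology;
    the new root bisects that edge 50/50.  Tags are dropped (node identities
    change); total branch length and the unrooted split set are preserved.
    """
    outgroup = frozenset(outgroup)
    all_taxa = tree.taxa
    unknown = sorted(outgroup - all_taxa)
    if unknown:
        raise TreeError(f"unknown taxa in outgroup: {unknown}")
    if not outgroup or outgroup == all_taxa:
        raise TreeError("outgroup must be a non-empty proper subset of taxa")

    # undirected adjacency, suppressing a degree-2 old root
    adj: dict[int, dict[int, float]] = {v: {} for v in range(tree.n_nodes)}
    for v in range(tree.n_nodes):
        p = int(tree.parent[v])
        if p >= 0:
            adj[v][p] = float(tree.blen[v])
            adj[p][v] = float(tree.blen[v])
    old_root = tree.root
    if len(adj[old_root]) == 2:
        (a, la), (b, lb) = adj[old_root].items()
        del adj[a][old_root], adj[b][old_root]
        adj[a][b] = la + lb
        adj[b][a] = la + lb
        adj[old_root] = {}

    # orient from an arbitrary tip to enumerate edges with below-sets
    start = tree.tips()[0]
    order: list[int] = []
    par: dict[int, int] = {start: -1}
    stack = [start]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adj[v]:
            if w != par[v]:
                par[w] = v
                stack.append(w)
    below: dict[int, frozenset[str]] = {}
    for v in reversed(order):
        acc = frozenset([tree.tip_labels[v]]) if v in tree.tip_labels else frozenset()
        for w in adj[v]:
            if w != par[v]:
                acc |= below[w]
        below[v] = acc

    split_edge = None
    for v in order:
        if par[v] < 0:
            continue
        if below[v] == outgroup or below[v] == all_taxa - outgroup:
            split_edge = (par[v], v)
            break
    if split_edge is None:
        clade = tree.tipset_below()[tree.mrca(outgroup)]
        extra = sorted(clade - outgroup)
        raise TreeError(
            "outgroup is not a clade on any edge; smallest containing clade "
            f"additionally holds: {extra}"
        )

    u, v = split_edge
    length = adj[u][v]
    new_root = tree.n_nodes  # fresh id
    del adj[u][v], adj[v][u]
    adj[new_root] = {u: length / 2.0, v: length / 2.0}
    adj[u][new_root] = length / 2.0
    adj[v][new_root] = length / 2.0

    # orient from the new root; keep only reachable (old root may be orphaned)
    par2: dict[int, int] = {new_root: -1}
    elen: dict[int, float] = {new_root: 0.0}
    order2 = [new_root]
    stack = [new_root]
    while stack:
        x = stack.pop()
        for w, lw in adj[x].items():
            if w != par2[x]:
                par2[w] = x
                elen[w] = lw
                order2.append(w)
                stack.append(w)

    remap = {old: new for new, old in enumerate(order2)}
    n = len(order2)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n, dtype=float)
    children: list[list[int]] = [[] for _ in range(n)]
    tip_labels: dict[int, str] = {}
    for old in order2:
        new = remap[old]
        if par2[old] >= 0:
            parent[new] = remap[par2[old]]
            children[remap[par2[old]]].append(new)
            blen[new] = elen[old]
        if old in tree.tip_labels:
            tip_labels[new] = tree.tip_labels[old]
    out = RootedTree(parent=parent, children=children, blen=blen,
                     tip_labels=tip_labels)
    out.validate()
    return out


# -- branch manipulation -------------------------------------------------

def scale_branches(tree: RootedTree, target_mean: float) -> RootedTree:
    """Rescale all branch lengths so their mean equals *target_mean*.

    Mirrors the BayesTraits-recommended preprocessing (tree scaled to a mean
    branch length of 0.1 before rate inference).
    """
    if target_mean <= 0:
        raise TreeError("target mean must be positive")
    out = tree.copy()
    r = out.root
    mask = np.ones(out.n_nodes, dtype=bool)
    mask[r] = False
    mean = float(out.blen[mask].mean())
    if mean == 0.0:
        raise TreeError("all branch lengths are zero; cannot rescale")
    out.blen[mask] *= target_mean / mean
    return out


def replace_zero_branches(tree: RootedTree, epsilon: float = ZERO_BRANCH_EPSILON,
                          log: list | None = None) -> RootedTree:
    """Replace exactly-zero non-root branches by *epsilon* (logged)."""
    out = tree.copy()
    r = out.root
    for v in range(out.n_nodes):
        if v != r and out.blen[v] == 0.0:
            out.blen[v] = epsilon
            if log is not None:
                log.append(v)
    return out


def tag_mrca(tree: RootedTree, name: str, taxa) -> RootedTree:
    """Return a copy with ``node_tags[name]`` set to the MRCA of *taxa*."""
    taxa = list(taxa)
    unknown = sorted(set(taxa) - tree.taxa)
    if unknown:
        raise TreeError(f"unknown taxa: {unknown}")
    out = tree.copy()
    out.node_tags[name] = out.mrca(taxa)
    return out


def read_tag_file(tree: RootedTree, path) -> RootedTree:
    """Apply a TSV tag file (``name<TAB>taxon1,taxon2,...``) to *tree*."""
    out = tree
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, taxa = line.split("\t")
            out = tag_mrca(out, name, [t.strip() for t in taxa.split(",")])
    return out
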