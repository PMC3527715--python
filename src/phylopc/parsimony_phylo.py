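"""Maximum-parsimony inference on binary haploid characters.

The lineage markers (mtDNA / Y-chromosome SNPs) are treated as binary
characters with optional missing states.  Tree length is the Fitch /
Hartigan parsimony score: the minimum number of 0<->1 changes over the tree
required to explain every character.  The search is heuristic — random
stepwise-addition sequences refined by nearest-neighbour-interchange (NNI)
hill-climbing, with parsimony-ratchet reweighting rounds and optional
subtree-prune-regraft (SPR) moves to escape local optima.  Equally
most-parsimonious trees are collected (deduplicated by their unrooted
bipartition sets, up to a cap) and merged by strict consensus; nodal
support comes from character bootstrap replicates; and poorly supported or
small clades are collapsed before assigning hierarchical clade identifiers
(``X1``, ``X21``, ...) used by the concordance stage.

The inner scoring loop packs each taxon's character states into two Python
integers (one bit per character for "may be 0" / "may be 1"), so a full
Fitch pass is a handful of bitwise operations per node regardless of the
number of characters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core_io import MISSING, CharacterMatrix, PhyloTree

__all__ = [
    "SearchResult",
    "fitch_length",
    "heuristic_search",
    "strict_consensus",
    "bootstrap_support",
    "collapse_and_label",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Exact parsimony length on an arbitrary (possibly multifurcating) tree
# ---------------------------------------------------------------------------

def fitch_length(tree: PhyloTree, chars: CharacterMatrix) -> int:
    """Parsimony length of ``tree`` for binary characters with missing data.

    Uses Hartigan's generalisation of the Fitch pass so multifurcating
    nodes (e.g. consensus trees) are scored exactly; a ``?`` tip state is
    the full state set {0, 1} and never forces a change.  The score is a
    property of the unrooted topology and does not depend on the rooting.
    """
    idx = {t: i for i, t in enumerate(chars.taxa)}
    m = chars.n_characters
    states = chars.states
    cost = 0
    sets: dict[int, np.ndarray] = {}  # node id -> (m, 2) bool
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            if label not in idx:
                raise KeyError(f"tip {label!r} has no character row")
            row = states[idx[label]]
            s = np.empty((m, 2), dtype=bool)
            s[:, 0] = (row == 0) | (row == MISSING)
            s[:, 1] = (row == 1) | (row == MISSING)
            sets[id(nd)] = s
        else:
            kids = nd.child_nodes()
            counts = np.zeros((m, 2), dtype=np.int64)
            for c in kids:
                counts += sets.pop(id(c))
            mx = counts.max(axis=1)
            cost += int((len(kids) - mx).sum())
            sets[id(nd)] = counts == mx[:, None]
    return cost


# ---------------------------------------------------------------------------
# Bit-packed character data and adjacency trees for the heuristic search
# ---------------------------------------------------------------------------

class _PackedChars:
    """Per-taxon state sets packed one character per bit."""

    def __init__(self, chars: CharacterMatrix, weights: np.ndarray | None = None):
        n, m = chars.states.shape
        self.n_taxa = n
        self.m = m
        self.full = (1 << m) - 1
        self.b0: list[int] = []
        self.b1: list[int] = []
        for row in chars.states:
            v0 = v1 = 0
            for j, s in enumerate(row):
                if s == 0 or s == MISSING:
                    v0 |= 1 << j
                if s == 1 or s == MISSING:
                    v1 |= 1 << j
            self.b0.append(v0)
            self.b1.append(v1)
        # characters with weight w > 1 contribute w-1 extra steps per change
        self.extra: list[tuple[int, int]] = []
        if weights is not None:
            for w in np.unique(weights):
                if w > 1:
                    mask = 0
                    for j in np.nonzero(weights == w)[0]:
                        mask |= 1 << int(j)
                    self.extra.append((mask, int(w) - 1))

    def count(self, empty: int) -> int:
        c = empty.bit_count()
        for mask, extra_w in self.extra:
            c += extra_w * (empty & mask).bit_count()
        return c


def _order_from(adj: dict[int, list[int]], root: int):
    """Preorder node list and parent map for ``adj`` rooted at tip ``root``."""
    parent = {root: -1}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    return order, parent


def _score_adj(adj: dict[int, list[int]], pc: _PackedChars, root: int = 0) -> int:
    """Exact Fitch length of a binary adjacency tree (rooted at tip ``root``)."""
    order, parent = _order_from(adj, root)
    s0: dict[int, int] = {}
    s1: dict[int, int] = {}
    full = pc.full
    steps = 0
    for u in reversed(order):
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            s0[u] = pc.b0[u]
            s1[u] = pc.b1[u]
            continue
        if u == root:  # root tip: fold its own states with its single subtree
            a0, a1 = pc.b0[u], pc.b1[u]
        else:
            a0, a1 = s0[kids[0]], s1[kids[0]]
            kids = kids[1:]
        for c in kids:
            i0 = a0 & s0[c]
            i1 = a1 & s1[c]
            empty = full & ~(i0 | i1)
            if empty:
                steps += pc.count(empty)
                a0 = i0 | (empty & (a0 | s0[c]))
                a1 = i1 | (empty & (a1 | s1[c]))
            else:
                a0, a1 = i0, i1
        s0[u] = a0
        s1[u] = a1
    return steps


def _combine(a0, a1, b0, b1, full):
    i0 = a0 & b0
    i1 = a1 & b1
    empty = full & ~(i0 | i1)
    return i0 | (empty & (a0 | b0)), i1 | (empty & (a1 | b1))


def _insertion_costs(adj, pc: _PackedChars, t0: int, t1: int, root: int = 0):
    """Greedy attachment cost of a new tip for every edge (parent, v).

    For each node ``v`` (other than the root tip) the edge above it gets the
    Fitch state set obtained by combining the subtree set below ``v`` with
    the context set of the rest of the tree; the cost of attaching the new
    tip there is the number of characters whose tip state set misses that
    edge set.  This is the standard greedy bound used for Wagner stepwise
    addition; final trees are always rescored exactly.
    """
    order, parent = _order_from(adj, root)
    s0: dict[int, int] = {}
    s1: dict[int, int] = {}
    full = pc.full
    for u in reversed(order):
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            s0[u] = pc.b0[u]
            s1[u] = pc.b1[u]
            continue
        if u == root:
            continue
        a0, a1 = s0[kids[0]], s1[kids[0]]
        for c in kids[1:]:
            a0, a1 = _combine(a0, a1, s0[c], s1[c], full)
        s0[u] = a0
        s1[u] = a1
    # context sets, preorder
    c0: dict[int, int] = {}
    c1: dict[int, int] = {}
    costs: list[tuple[int, int]] = []  # (cost, v) for edge (parent[v], v)
    for u in order:
        if u == root:
            continue
        p = parent[u]
        if p == root:
            c0[u], c1[u] = pc.b0[root], pc.b1[root]
        else:
            a0, a1 = c0[p], c1[p]
            for w in adj[p]:
                if w != parent[p] and w != u:
                    a0, a1 = _combine(a0, a1, s0[w], s1[w], full)
            c0[u], c1[u] = a0, a1
        f0, f1 = _combine(c0[u], c1[u], s0[u], s1[u], full)
        empty = full & ~((t0 & f0) | (t1 & f1))
        costs.append((pc.count(empty), u))
    return costs, parent


def _splits_of_adj(adj, n_taxa: int, root: int = 0) -> frozenset[frozenset[int]]:
    """Canonical nontrivial bipartition set (side not containing taxon 0)."""
    order, parent = _order_from(adj, root)
    below: dict[int, frozenset[int]] = {}
    for u in reversed(order):
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            below[u] = frozenset([u])
        else:
            acc: set[int] = set()
            for c in kids:
                acc |= below[c]
            below[u] = frozenset(acc)
    all_taxa = frozenset(range(n_taxa))
    out = set()
    for u in order:
        if u == root or u < n_taxa:
            continue
        side = below[u]
        if 0 in side:
            side = all_taxa - side
        if 2 <= len(side) <= n_taxa - 2:
            out.add(side)
    return frozenset(out)


def _replace(adj, node, old, new):
    lst = adj[node]
    lst[lst.index(old)] = new


def _nni_moves(adj, n_taxa):
    """All NNI moves as (u, b, v, c): swap neighbour b of u with c of v."""
    moves = []
    for u in adj:
        if u < n_taxa:
            continue
        for v in adj[u]:
            if v < n_taxa or v < u:
                continue
            a_side = [x for x in adj[u] if x != v]
            b_side = [x for x in adj[v] if x != u]
            moves.append((u, a_side[1], v, b_side[0]))
            moves.append((u, a_side[1], v, b_side[1]))
    return moves


def _swap(adj, u, b, v, c):
    _replace(adj, u, b, c)
    _replace(adj, v, c, b)
    _replace(adj, b, u, v)
    _replace(adj, c, v, u)


class _TreeSet:
    """Equal-best trees deduplicated by canonical bipartition set."""

    def __init__(self, n_taxa: int, cap: int):
        self.n_taxa = n_taxa
        self.cap = cap
        self.keys: set[frozenset[frozenset[int]]] = set()
        self.trees: list[dict[int, list[int]]] = []

    def add(self, adj) -> None:
        if len(self.trees) >= self.cap:
            return
        key = _splits_of_adj(adj, self.n_taxa)
        if key not in self.keys:
            self.keys.add(key)
            self.trees.append({u: list(vs) for u, vs in adj.items()})

    def reset(self) -> None:
        self.keys.clear()
        self.trees.clear()


def _random_addition(pc: _PackedChars, rng: np.random.Generator):
    """One random-addition-sequence starting tree (binary, unrooted)."""
    n = pc.n_taxa
    perm = [int(x) for x in rng.permutation(n)]
    nxt = n  # next internal node id
    hub = nxt
    nxt += 1
    adj: dict[int, list[int]] = {hub: perm[:3]}
    for t in perm[:3]:
        adj[t] = [hub]
    root = perm[0]
    for t in perm[3:]:
        costs, parent = _insertion_costs(adj, pc, pc.b0[t], pc.b1[t], root=root)
        best = min(c for c, _ in costs)
        v = next(v for c, v in costs if c == best)
        p = parent[v]
        w = nxt
        nxt += 1
        _replace(adj, p, v, w)
        _replace(adj, v, p, w)
        adj[w] = [p, v, t]
        adj[t] = [w]
    return adj


def _nni_climb(adj, pc, best_len, ties: _TreeSet | None, rng=None):
    """First-improvement NNI hill climb; records equal-length neighbours."""
    improved = True
    while improved:
        improved = False
        for (u, b, v, c) in _nni_moves(adj, pc.n_taxa):
            _swap(adj, u, b, v, c)
            s = _score_adj(adj, pc)
            if s < best_len:
                best_len = s
                if ties is not None:
                    ties.reset()
                    ties.add(adj)
                improved = True
                break
            if s == best_len and ties is not None:
                ties.add(adj)
            _swap(adj, u, c, v, b)  # revert
    return best_len


def _spr_round(adj, pc, best_len, rng, n_attempts: int):
    """Random subtree-prune-regraft attempts, keeping improvements."""
    n = pc.n_taxa
    for _ in range(n_attempts):
        internal = [u for u in adj if u >= n]
        if not internal:
            break
        u = int(rng.choice(internal))
        # prune the subtree hanging from a random neighbour of u
        v = adj[u][int(rng.integers(len(adj[u])))]
        rest = [x for x in adj[u] if x != v]
        if len(rest) != 2:
            continue
        a, b = rest
        saved = {k: list(adj[k]) for k in (u, v, a, b)}
        _replace(adj, a, u, b)
        _replace(adj, b, u, a)
        # candidate regraft edges: any edge not incident to u or v
        edges = [(x, y) for x in adj for y in adj[x]
                 if x < y and u not in (x, y) and v not in (x, y)]
        if not edges:
            adj.update(saved)
            continue
        x, y = edges[int(rng.integers(len(edges)))]
        _replace(adj, x, y, u)
        _replace(adj, y, x, u)
        adj[u] = [x, y, v]
        s = _score_adj(adj, pc)
        if s < best_len:
            best_len = s
        else:
            _replace(adj, x, u, y)
            _replace(adj, y, u, x)
            for k, vs in saved.items():
                adj[k] = vs
    return best_len


def _adj_to_newick(adj, taxa, root_tip: int = 0) -> str:
    """Unrooted adjacency tree as Newick rooted at taxon 0's neighbour."""
    start = adj[root_tip][0]

    def rec(u, parent):
        kids = [v for v in adj[u] if v != parent]
        if not kids:
            return taxa[u]
        return "(" + ",".join(rec(v, u) for v in kids) + ")"

    parts = [rec(v, start) for v in adj[start]]
    return "(" + ",".join(parts) + ");"


# ---------------------------------------------------------------------------
# Heuristic search
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    """Equally most-parsimonious trees found by the heuristic search."""

    best_trees: list[PhyloTree]
    best_length: int
    n_addition_sequences: int
    seed: int
    splits_keys: list[frozenset] = field(default_factory=list, repr=False)


def heuristic_search(
    chars: CharacterMatrix,
    n_additions: int = 10,
    ratchet_iters: int = 4,
    seed: int = 0,
    max_trees: int = 100,
    use_spr: bool = False,
    spr_attempts: int = 20,
) -> SearchResult:
    """Random-addition + NNI (+ ratchet, optional SPR) parsimony search.

    Each addition sequence inserts taxa in random order at the greedily
    cheapest edge, then hill-climbs with NNI under exact Fitch scoring.
    Ratchet rounds temporarily double the weight of a random quarter of the
    characters, climb under the perturbed score, then climb again under
    equal weights, accepting improvements.  All trees attaining the best
    length found are kept, deduplicated by unrooted bipartition set, up to
    ``max_trees``.  Deterministic for a given ``seed``.
    """
    if chars.n_taxa < 4:
        raise ValueError("need at least 4 taxa for a non-trivial topology")
    rng = np.random.default_rng(seed)
    pc = _PackedChars(chars)
    m = chars.n_characters
    global_best = None
    ties = _TreeSet(chars.n_taxa, max_trees)

    for _ in range(n_additions):
        adj = _random_addition(pc, rng)
        length = _score_adj(adj, pc)
        local = _TreeSet(chars.n_taxa, max_trees)
        length = _nni_climb(adj, pc, length, local)
        local.add(adj)
        if use_spr:
            length = _spr_round(adj, pc, length, rng, spr_attempts)
            length = _nni_climb(adj, pc, length, local)
            local.add(adj)
        for _ in range(ratchet_iters):
            weights = np.ones(m, dtype=np.int64)
            boost = rng.random(m) < 0.25
            weights[boost] = 2
            pcw = _PackedChars(chars, weights)
            pcw.b0, pcw.b1 = pc.b0, pc.b1  # same states, new weights
            work = {u: list(vs) for u, vs in adj.items()}
            wlen = _score_adj(work, pcw)
            wlen = _nni_climb(work, pcw, wlen, None)
            plen = _score_adj(work, pc)
            plen = _nni_climb(work, pc, plen, local)
            if plen < length:
                length = plen
                adj = work
                local.reset()
                local.add(adj)
            elif plen == length:
                local.add(work)
        if global_best is None or length < global_best:
            global_best = length
            ties.reset()
        if length == global_best:
            for t in local.trees:
                if _score_adj(t, pc) == global_best:
                    ties.add(t)

    trees = [
        PhyloTree.from_newick(_adj_to_newick(t, chars.taxa))
        for t in ties.trees
    ]
    return SearchResult(
        best_trees=trees,
        best_length=int(global_best),
        n_addition_sequences=n_additions,
        seed=seed,
        splits_keys=list(ties.keys),
    )


# ---------------------------------------------------------------------------
# Strict consensus
# ---------------------------------------------------------------------------

def strict_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the bipartitions shared by every input tree."""
    if not trees:
        raise ValueError("no trees given")
    tipsets = [frozenset(t.tip_labels) for t in trees]
    if len(set(tipsets)) != 1:
        raise ValueError("trees have mismatched tip sets")
    tips = sorted(tipsets[0])
    shared = trees[0].splits()
    for t in trees[1:]:
        shared &= t.splits()
    return _tree_from_splits(tips, shared)


def _tree_from_splits(tips: list[str], splits: set[frozenset[str]]) -> PhyloTree:
    """Build a rooted tree realising a compatible set of splits.

    The root corresponds to the full tip set; each split becomes the clade
    on the side away from the lexicographically smallest tip.
    """
    groups = sorted(splits, key=len, reverse=True)
    taxon_ns = dendropy.TaxonNamespace(tips)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    owner: dict[frozenset[str], dendropy.Node] = {frozenset(tips): root}
    chain: list[tuple[frozenset[str], dendropy.Node]] = [(frozenset(tips), root)]
    for grp in groups:
        # smallest already-built group containing grp (groups sorted by size)
        parent = root
        parent_set = frozenset(tips)
        for s, node in chain:
            if grp < s and len(s) < len(parent_set):
                parent, parent_set = node, s
        nd = dendropy.Node()
        parent.add_child(nd)
        owner[grp] = nd
        chain.append((grp, nd))
    for tip in tips:
        parent = root
        parent_set = frozenset(tips)
        for s, node in chain:
            if tip in s and len(s) < len(parent_set):
                parent, parent_set = node, s
        leaf = dendropy.Node(taxon=taxon_ns.get_taxon(tip))
        parent.add_child(leaf)
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Bootstrap support
# ---------------------------------------------------------------------------

def bootstrap_support(
    chars: CharacterMatrix,
    reference: PhyloTree,
    n_reps: int = 1000,
    seed: int = 0,
    n_additions: int = 1,
    ratchet_iters: int = 0,
    max_trees: int = 20,
) -> PhyloTree:
    """Percent of character-bootstrap replicates supporting each reference node.

    Characters are resampled with replacement; each replicate is searched
    with the same machinery as the main analysis and a node counts as
    recovered when its bipartition appears in the replicate's strict
    consensus (i.e. in every equally best replicate tree).  Trivial
    bipartitions get support 100 by construction.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    taxa = chars.taxa
    name_to_idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)

    ref_nodes = []
    out = reference.copy()
    all_tips = frozenset(out.tip_labels)
    for nd in out.internal_nodes():
        if nd is out.dendropy_tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        ref_nodes.append((nd, side))

    counts = {id(nd): 0 for nd, _ in ref_nodes}
    for _ in range(n_reps):
        cols = rng.integers(0, chars.n_characters, size=chars.n_characters)
        rep = CharacterMatrix(taxa=list(taxa), states=chars.states[:, cols])
        res = heuristic_search(
            rep,
            n_additions=n_additions,
            ratchet_iters=ratchet_iters,
            seed=int(rng.integers(2**31)),
            max_trees=max_trees,
        )
        shared: frozenset | None = None
        for key in res.splits_keys:
            shared = key if shared is None else (shared & key)
        shared = shared or frozenset()
        # translate index splits back to label splits
        rep_splits = set()
        for s in shared:
            rep_splits.add(frozenset(taxa[i] for i in s))
        for nd, side in ref_nodes:
            sz = len(side)
            if sz <= 1 or sz >= n - 1:
                counts[id(nd)] += 1
                continue
            key = side if taxa[0] not in side else all_tips - side
            if frozenset(key) in rep_splits:
                counts[id(nd)] += 1

    for nd, _ in ref_nodes:
        nd.label = f"{100.0 * counts[id(nd)] / n_reps:g}"
    return out


# ---------------------------------------------------------------------------
# Collapse and hierarchical labelling
# ---------------------------------------------------------------------------

def collapse_and_label(
    tree: PhyloTree,
    min_support: float = 70.0,
    min_size: int = 5,
    outgroup: str | None = None,
) -> PhyloTree:
    """Root on the outgroup, collapse weak/small nodes, assign clade ids.

    Every internal node (root excluded) with bootstrap support below
    ``min_support`` percent *or* fewer than ``min_size`` descendant tips is
    collapsed into its parent.  Surviving internal nodes get hierarchical
    identifiers: the root's retained children are ``X1``, ``X2``, ... and a
    node's identifier is its parent's identifier plus its 1-based position
    among that parent's children, ordered by descending descendant-tip
    count (ties by smallest tip label).  An ancestor's identifier is
    therefore always a prefix of its descendants'.
    """
    out = tree.copy()
    dt = out.dendropy_tree
    if outgroup is not None:
        matches = [lf for lf in dt.leaf_node_iter() if lf.taxon.label == outgroup]
        if not matches:
            raise ValueError(f"outgroup {outgroup!r} is not a tip of the tree")
        og = matches[0]
        if og.parent_node is not dt.seed_node:
            # supports are attached to nodes but belong to bipartitions, so
            # stash them by (outgroup-free) tip set and restore after rerooting
            tips = frozenset(out.tip_labels)
            bip_label: dict[frozenset[str], str | None] = {}
            for nd in out.internal_nodes():
                if nd is dt.seed_node:
                    continue
                side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                key = side if outgroup not in side else tips - side
                bip_label[key] = nd.label
            dt.reroot_at_node(og.parent_node, update_bipartitions=False,
                              suppress_unifurcations=True)
            for nd in out.internal_nodes():
                if nd is dt.seed_node:
                    continue
                side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                key = side if outgroup not in side else tips - side
                nd.label = bip_label.get(key)

    # collapse pass (postorder so sizes are stable while editing)
    for nd in list(dt.postorder_node_iter()):
        if nd.is_leaf() or nd is dt.seed_node:
            continue
        support = PhyloTree.node_support(nd)
        size = sum(1 for _ in nd.leaf_iter())
        if support is None or support < min_support or size < min_size:
            nd.edge.collapse()

    # hierarchical labels
    def order_key(child: dendropy.Node):
        tips = [lf.taxon.label for lf in child.leaf_iter()]
        return (-len(tips), min(tips))

    def assign(node: dendropy.Node, prefix: str) -> None:
        kids = sorted(node.child_nodes(), key=order_key)
        for i, child in enumerate(kids, start=1):
            if child.is_leaf():
                continue
            child.label = f"{prefix}{i}"
            assign(child, child.label)

    dt.seed_node.label = None
    assign(dt.seed_node, "X")
    return out
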