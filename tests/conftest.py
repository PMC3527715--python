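"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, direct
formula evaluation) and share no code with the package internals they
check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from phylopc.core_io import MISSING, CharacterMatrix, GenotypeMatrix, PhyloTree


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def make_genotypes(values, ploidy: str = "diploid",
                   populations=None) -> GenotypeMatrix:
    values = np.asarray(values)
    n, m = values.shape
    snp = pd.DataFrame({
        "id": [f"rs{j}" for j in range(m)],
        "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1),
        "allele1": ["A"] * m,
        "allele2": ["G"] * m,
    })
    smp = pd.DataFrame({
        "id": [f"S{i}" for i in range(n)],
        "sex": ["M"] * n,
        "population": populations if populations is not None else ["U"] * n,
    })
    return GenotypeMatrix(values=values, ploidy=ploidy, snp_meta=snp,
                          sample_meta=smp)


def random_newick(rng: np.random.Generator, labels: list[str],
                  lengths: bool = False) -> str:
    """Random binary rooted tree by sequential joining."""
    nodes = [f"{l}:{rng.uniform(0.5, 2):.3f}" if lengths else l for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        if lengths:
            merged += f":{rng.uniform(0.5, 2):.3f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


# ---------------------------------------------------------------------------
# Parsimony oracles
# ---------------------------------------------------------------------------

def exhaustive_fitch(tree: PhyloTree, chars: CharacterMatrix) -> int:
    """Minimum changes over all assignments of internal (and missing-tip)
    states — brute force, independent of any Fitch/Hartigan pass."""
    dt = tree.dendropy_tree
    nodes = list(dt.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    edges = [
        (index[id(nd.parent_node)], index[id(nd)])
        for nd in nodes
        if nd.parent_node is not None
    ]
    taxon_row = {t: i for i, t in enumerate(chars.taxa)}
    total = 0
    for j in range(chars.n_characters):
        fixed: dict[int, int] = {}
        free: list[int] = []
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                s = chars.states[taxon_row[nd.taxon.label], j]
                if s == MISSING:
                    free.append(i)
                else:
                    fixed[i] = int(s)
            else:
                free.append(i)
        best = None
        for assign in itertools.product((0, 1), repeat=len(free)):
            state = dict(fixed)
            state.update(zip(free, assign))
            cost = sum(1 for a, b in edges if state[a] != state[b])
            if best is None or cost < best:
                best = cost
        total += best
    return total


def all_unrooted_newicks(labels: list[str]) -> list[str]:
    """Every unrooted binary topology on the labels, as Newick strings.

    Built by sequential edge insertion on an independent nested-list
    representation (1, 3, 15, 105 ... topologies for 3, 4, 5, 6 taxa).
    """
    # tree = dict adjacency over string node ids
    def insert_all(adj, new_label, counter):
        out = []
        edges = {tuple(sorted((a, b))) for a in adj for b in adj[a]}
        for a, b in edges:
            new_adj = {k: list(v) for k, v in adj.items()}
            mid = f"_i{counter}"
            new_adj[a][new_adj[a].index(b)] = mid
            new_adj[b][new_adj[b].index(a)] = mid
            new_adj[mid] = [a, b, new_label]
            new_adj[new_label] = [mid]
            out.append(new_adj)
        return out

    first = {"_i0": labels[:3], labels[0]: ["_i0"], labels[1]: ["_i0"],
             labels[2]: ["_i0"]}
    trees = [first]
    for k, lab in enumerate(labels[3:], start=1):
        trees = [t for adj in trees for t in insert_all(adj, lab, k)]

    def to_newick(adj):
        start = adj[labels[0]][0]

        def rec(u, parent):
            kids = [v for v in adj[u] if v != parent]
            if not kids:
                return u
            return "(" + ",".join(rec(v, u) for v in kids) + ")"

        return "(" + ",".join(rec(v, start) for v in adj[start]) + ");"

    return [to_newick(t) for t in trees]


# ---------------------------------------------------------------------------
# FDR oracles (direct formula evaluation)
# ---------------------------------------------------------------------------

def bh_direct(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


def storey_direct(pvals: np.ndarray, pi0: float) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pi0 * m * p[i] / rank)
        q[i] = min(max(running, 0.0), 1.0)
    return q
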