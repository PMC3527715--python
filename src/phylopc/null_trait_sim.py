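"""Brownian-motion simulation of null phenotypes on inferred trees.

A continuous trait evolves from a root value of 0; along each branch the
change is drawn ``Normal(0, rate * branch_length)``, so two tips covary in
proportion to their shared root-to-ancestor path length.  Simulating many
such traits on the equally most-parsimonious trees yields phenotypes that
are correlated with population structure but, by construction, independent
of any individual SNP — the null datasets used to measure Type I error of
the correction strategies.

Parsimony trees carry no branch lengths; by default every edge is assigned
unit length (the usual convention for trait simulation on cladograms),
which can be overridden by supplying trees with explicit lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import PhyloTree

__all__ = ["TraitDataset", "simulate_trait", "simulate_batch"]


@dataclass
class TraitDataset:
    """One simulated null phenotype over the tips of a tree."""

    values: dict[str, float]
    rate: float
    seed: int
    tree_index: int = 0
    replicate: int = 0

    def vector(self, sample_ids: list[str]) -> np.ndarray:
        """Trait values aligned to a sample ordering."""
        try:
            return np.array([self.values[s] for s in sample_ids])
        except KeyError as exc:
            raise KeyError(f"trait has no value for sample {exc}") from None


def simulate_trait(
    tree: PhyloTree,
    rate: float = 1.0,
    seed: int = 0,
    tree_index: int = 0,
    replicate: int = 0,
) -> TraitDataset:
    """Evolve one trait down the tree by Brownian motion (root value 0)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    work = tree if tree.has_branch_lengths else tree.with_unit_branch_lengths()
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    state: dict[int, float] = {}
    for nd in work.dendropy_tree.preorder_node_iter():
        if nd.parent_node is None:
            state[id(nd)] = 0.0
        else:
            bl = nd.edge.length
            if bl is None:
                bl = 1.0
            if bl < 0:
                raise ValueError(f"negative branch length {bl}")
            step = rng.normal(0.0, np.sqrt(rate * bl)) if bl > 0 else 0.0
            state[id(nd)] = state[id(nd.parent_node)] + step
        if nd.is_leaf():
            values[nd.taxon.label] = state[id(nd)]
    return TraitDataset(values=values, rate=rate, seed=seed,
                        tree_index=tree_index, replicate=replicate)


def simulate_batch(
    trees: list[PhyloTree],
    reps_per_tree: int = 15,
    rate: float = 1.0,
    seed: int = 0,
) -> list[TraitDataset]:
    """``len(trees) * reps_per_tree`` independent traits, seeded from one master.

    Per-dataset seeds are derived deterministically from the master seed so
    the whole batch is reproducible and datasets are mutually independent.
    """
    if reps_per_tree < 1:
        raise ValueError("reps_per_tree must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(trees) * reps_per_tree) % (2**31)
    out: list[TraitDataset] = []
    k = 0
    for ti, tree in enumerate(trees):
        if not tree.has_branch_lengths:
            tree = tree.with_unit_branch_lengths()
        for rep in range(reps_per_tree):
            out.append(
                simulate_trait(
                    tree, rate=rate, seed=int(child_seeds[k]),
                    tree_index=ti, replicate=rep,
                )
            )
            k += 1
    return out
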