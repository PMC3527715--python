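"""Domain types and file I/O.

The package works with three kinds of objects:

* :class:`GenotypeMatrix` — diploid autosomal (0/1/2) or haploid lineage
  (0/1) genotypes for a cohort, read from and written to Eigenstrat
  ``geno``/``snp``/``ind`` triplets (missing code ``9`` in the files,
  ``-1`` in memory).
* :class:`PhyloTree` — a rooted tree over sample ids, with optional branch
  lengths, bootstrap support carried as internal-node labels (the common
  Newick dialect) and, after collapsing, hierarchical clade identifiers.
* :class:`CladeAssociationTable` — the clades-by-components record of which
  principal components predict membership in which clade, with the refit
  logistic coefficient, standard error and p-value in each occupied cell.

A transcription of the published clade/component association table for the
HapMap + African-American cohort ships as a packaged fixture
(:func:`load_table1_fixture`) so the count-and-cutoff selection step can be
re-run without the original genotype data.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "CharacterMatrix",
    "PhyloTree",
    "AssociationCell",
    "CladeAssociationTable",
    "read_eigenstrat",
    "write_eigenstrat",
    "read_newick",
    "write_newick",
    "load_table1_fixture",
]

#: In-memory code for a missing genotype (files use the Eigenstrat code 9).
MISSING = -1


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Genotype containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples-by-SNPs genotype matrix with per-SNP and per-sample metadata.

    Parameters
    ----------
    values
        Integer array of shape ``(n_samples, n_snps)``.  Diploid entries are
        minor-allele counts in ``{0, 1, 2}``; haploid entries in ``{0, 1}``;
        missing entries are ``MISSING`` (-1).
    ploidy
        ``"diploid"`` or ``"haploid"``.
    snp_meta
        DataFrame with columns ``id``, ``chrom``, ``pos`` (1-based),
        ``allele1``, ``allele2``; one row per SNP.
    sample_meta
        DataFrame with columns ``id``, ``sex`` and optionally
        ``population``; one row per sample.
    """

    values: np.ndarray
    ploidy: str
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x SNPs)")
        if self.ploidy not in ("diploid", "haploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        n, m = self.values.shape
        if len(self.sample_meta) != n:
            raise ValueError(
                f"sample_meta has {len(self.sample_meta)} rows for {n} samples"
            )
        if len(self.snp_meta) != m:
            raise ValueError(f"snp_meta has {len(self.snp_meta)} rows for {m} SNPs")
        top = 2 if self.ploidy == "diploid" else 1
        vals = self.values
        bad = (vals != MISSING) & ((vals < 0) | (vals > top))
        if bad.any():
            raise ValueError(f"genotype entries outside [0, {top}] or missing code")
        for frame, col in ((self.snp_meta, "SNP"), (self.sample_meta, "sample")):
            ids = frame["id"]
            if ids.duplicated().any():
                raise ValueError(f"duplicate {col} ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta["id"])

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta["id"])

    def to_character_matrix(self) -> "CharacterMatrix":
        """View a haploid matrix as a parsimony character matrix."""
        if self.ploidy != "haploid":
            raise ValueError("only haploid matrices convert to characters")
        return CharacterMatrix(taxa=self.sample_ids, states=self.values.copy())


@dataclass
class CharacterMatrix:
    """Binary character matrix for parsimony analysis.

    ``states`` is ``(n_taxa, n_characters)`` over ``{0, 1}`` with ``-1``
    for unknown ('?').
    """

    taxa: list[str]
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise ValueError("states must be (n_taxa, n_characters)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa must be unique")
        vals = self.states
        if (((vals != MISSING) & ((vals < 0) | (vals > 1)))).any():
            raise ValueError("character states must be 0, 1 or missing")
        if (vals == MISSING).all(axis=1).any():
            raise ValueError("taxon with all states unknown")

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class PhyloTree:
    """Rooted tree over sample ids, backed by a dendropy tree.

    Internal-node Newick labels carry either bootstrap support (numeric,
    percent in [0, 100]) or, after collapsing, hierarchical clade
    identifiers such as ``X21`` (non-numeric strings).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise FormatError(f"invalid Newick: {exc}") from exc
        return cls(t)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip() + "\n"

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    # -- basic queries -------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def internal_nodes(self, exclude_root: bool = False) -> list[dendropy.Node]:
        return [
            nd
            for nd in self._tree.preorder_node_iter()
            if not nd.is_leaf() and not (exclude_root and nd is self._tree.seed_node)
        ]

    @staticmethod
    def node_support(node: dendropy.Node) -> float | None:
        """Bootstrap support parsed from a numeric internal-node label."""
        if node.label is None:
            return None
        try:
            return float(node.label)
        except ValueError:
            return None

    @property
    def has_branch_lengths(self) -> bool:
        return all(
            nd.edge.length is not None
            for nd in self._tree.preorder_node_iter()
            if nd.parent_node is not None
        )

    def with_unit_branch_lengths(self) -> "PhyloTree":
        out = self.copy()
        for nd in out._tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = 1.0
        return out

    # -- clades ---------------------------------------------------------

    @property
    def clades(self) -> dict[str, dendropy.Node]:
        """Mapping of clade identifier to internal node (non-numeric labels)."""
        out: dict[str, dendropy.Node] = {}
        for nd in self.internal_nodes():
            if nd.label is not None and self.node_support(nd) is None:
                if nd.label in out:
                    raise ValueError(f"duplicate clade id {nd.label!r}")
                out[nd.label] = nd
        return out

    def clade_tips(self, clade_id: str) -> list[str]:
        try:
            node = self.clades[clade_id]
        except KeyError:
            raise KeyError(f"unknown clade id {clade_id!r}") from None
        return [lf.taxon.label for lf in node.leaf_iter()]

    # -- splits ----------------------------------------------------------

    def splits(self, nontrivial_only: bool = True) -> set[frozenset[str]]:
        """Unrooted bipartitions, each encoded as the tip set on the side
        not containing the lexicographically smallest tip."""
        tips = frozenset(self.tip_labels)
        anchor = min(tips)
        out: set[frozenset[str]] = set()
        for nd in self.internal_nodes():
            side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if anchor in side:
                side = tips - side
            if nontrivial_only and (len(side) < 2 or len(side) > len(tips) - 2):
                continue
            out.add(side)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (supports as internal-node labels)."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------------
# Eigenstrat triplet
# ---------------------------------------------------------------------------

def read_eigenstrat(geno_path, snp_path, ind_path, ploidy: str = "diploid") -> GenotypeMatrix:
    """Read an Eigenstrat ``geno``/``snp``/``ind`` triplet.

    The geno file has one line per SNP and one character per sample over
    ``{0, 1, 2, 9}`` (``{0, 1, 9}`` for haploid data); 9 is missing.
    The returned matrix is transposed to samples x SNPs.
    """
    ind = pd.read_csv(
        ind_path, sep=r"\s+", header=None, names=["id", "sex", "population"],
        dtype=str,
    )
    snp = pd.read_csv(snp_path, sep=r"\s+", header=None, dtype=str)
    if snp.shape[1] == 6:
        snp.columns = ["id", "chrom", "gpos", "pos", "allele1", "allele2"]
    elif snp.shape[1] == 4:
        snp.columns = ["id", "chrom", "gpos", "pos"]
        snp["allele1"], snp["allele2"] = "A", "G"
    else:
        raise FormatError(f"snp file has {snp.shape[1]} columns; expected 4 or 6")
    snp_meta = snp[["id", "chrom", "pos", "allele1", "allele2"]].copy()
    snp_meta["pos"] = snp_meta["pos"].astype(int)

    n_samples = len(ind)
    top = "2" if ploidy == "diploid" else "1"
    allowed = set("019") | ({"2"} if ploidy == "diploid" else set())
    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_samples:
                raise FormatError(
                    f"geno line {lineno} has {len(line)} entries for "
                    f"{n_samples} samples"
                )
            bad = set(line) - allowed
            if bad:
                raise FormatError(
                    f"geno line {lineno}: unknown character(s) {sorted(bad)} "
                    f"(alleles must be 0..{top} or 9)"
                )
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    values = np.asarray(rows, dtype=np.int16).T  # samples x SNPs
    values[values == 9] = MISSING
    if values.shape[1] != len(snp_meta):
        raise FormatError(
            f"geno has {values.shape[1]} SNPs but snp file has {len(snp_meta)}"
        )
    return GenotypeMatrix(values=values, ploidy=ploidy, snp_meta=snp_meta,
                          sample_meta=ind)


def write_eigenstrat(g: GenotypeMatrix, geno_path, snp_path, ind_path) -> None:
    """Write a genotype matrix as an Eigenstrat triplet (missing -> 9)."""
    vals = g.values.T.copy()  # SNPs x samples
    vals[vals == MISSING] = 9
    with open(geno_path, "w") as fh:
        for row in vals:
            fh.write("".join(map(str, row)) + "\n")
    with open(snp_path, "w") as fh:
        for _, r in g.snp_meta.iterrows():
            fh.write(f"{r['id']}\t{r['chrom']}\t0.0\t{r['pos']}\t{r['allele1']}\t{r['allele2']}\n")
    with open(ind_path, "w") as fh:
        for _, r in g.sample_meta.iterrows():
            pop = r.get("population", "U")
            if pop is None or (isinstance(pop, float) and math.isnan(pop)):
                pop = "U"
            fh.write(f"{r['id']}\t{r['sex']}\t{pop}\n")


# ---------------------------------------------------------------------------
# Clade association table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationCell:
    """Refit logistic coefficient for one (clade, component) pair."""

    p: float
    beta: float | None = None
    se: float | None = None
    separation: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")
        if self.se is not None and self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass
class CladeAssociationTable:
    """Sparse clades-by-components table of selected associations.

    ``cells[(clade_id, component)]`` is present only where the best-subset
    procedure selected the component for that clade.  Components are
    1-based indices into the principal-component ordering.
    """

    clades: list[str]
    components: list[int]
    cells: dict[tuple[str, int], AssociationCell] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (clade, comp) in self.cells:
            if clade not in self.clades:
                raise ValueError(f"cell references unknown clade {clade!r}")
            if comp not in self.components:
                raise ValueError(f"cell references unknown component {comp}")

    def counts(self) -> dict[int, int]:
        """Number of clades in which each component was selected."""
        out = {c: 0 for c in self.components}
        for (_, comp) in self.cells:
            out[comp] += 1
        return out

    def to_tsv(self) -> str:
        """Clades as columns, components as rows; empty cell = not selected."""
        lines = ["component\t" + "\t".join(self.clades)]
        for comp in self.components:
            row = [str(comp)]
            for clade in self.clades:
                cell = self.cells.get((clade, comp))
                row.append("." if cell is None else f"{cell.p:.3g}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "CladeAssociationTable":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
        clades = list(df.columns[1:])
        components = [int(c) for c in df.iloc[:, 0]]
        cells: dict[tuple[str, int], AssociationCell] = {}
        for _, row in df.iterrows():
            comp = int(row.iloc[0])
            for clade in clades:
                val = row[clade]
                if isinstance(val, str) and val.strip() != ".":
                    cells[(clade, comp)] = AssociationCell(p=float(val))
        return cls(clades=clades, components=components, cells=cells)


def load_table1_fixture() -> CladeAssociationTable:
    """Published clade/component association table for the HapMap +
    African-American cohort (10 printed clades, 16 components; cells carry
    the printed p-value magnitudes)."""
    try:
        text = resources.files("phylopc.data").joinpath("table1.tsv").read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise RuntimeError("packaged association-table fixture missing") from exc
    table = CladeAssociationTable.from_tsv(text)
    if len(table.clades) != 10:
        raise RuntimeError("association-table fixture corrupt: clade count")
    return table
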