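"""Synthetic cohorts with known population structure.

Emulates the study design the method targets: a multi-population cohort
(including one admixed group) genotyped for many autosomal SNPs plus a
small panel of haploid lineage markers whose phylogenetic signal mirrors
the population history.

Autosomal genotypes follow the Balding-Nichols model: each SNP draws an
ancestral frequency ``p ~ Uniform(0.1, 0.9)``; each population draws its
own frequency from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with its
differentiation parameter ``F``; individuals are ``Binomial(2, p_pop)``.
Admixed individuals use the mixture frequency ``alpha * p_src1 +
(1-alpha) * p_src2``.

Haploid markers are generated as a perfect phylogeny plus noise: each
marker mutates (0 -> 1) on one branch of the population tree chosen with
probability proportional to branch length, every sample inherits its
population's root-to-tip mutation set, and per-sample private mutations
(Poisson-many random flips) add homoplasy.  Admixed samples inherit the
haplotype of one source population, chosen with probability ``alpha`` —
single-parent transmission, exactly what makes the lineage markers
informative about admixture history.

The default configuration mirrors the motivating cohort at desk scale:
45 + 23 + 23 + 53 reference individuals from four populations plus 90
admixed individuals, with 2,000 autosomal and 60 haploid SNPs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .core_io import CharacterMatrix, GenotypeMatrix
from .structure_pca import PCAResult

__all__ = [
    "Admixture",
    "DemographyConfig",
    "CohortBundle",
    "default_config",
    "hidden_structure_config",
    "simulate_autosomal",
    "simulate_haploid",
    "make_cohort",
    "component_separating",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Admixture:
    """One admixed population drawing from two sources with weight alpha."""

    target: str
    sources: tuple[str, str]
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class DemographyConfig:
    """Demography of a synthetic cohort.

    ``population_tree`` is a Newick string over haploid *lineages*; branch
    lengths (arbitrary drift units) weight where haploid mutations land.
    A lineage tip named ``POP.k`` is the k-th maternal/paternal lineage
    segregating within autosomal population ``POP`` (lineage structure is
    routinely finer than autosomal structure — that is what makes the
    haploid markers informative); a tip named ``POP`` is a population with
    a single lineage.  ``fst`` gives each non-admixed population's
    Balding-Nichols differentiation from the shared ancestral pool.
    ``private_mutation_rate`` is the expected number of private haploid
    flips per sample.  ``admixture_heterogeneity`` > 0 gives each admixed
    individual its own ancestry proportion ``alpha_i ~ Beta(alpha*k,
    (1-alpha)*k)`` (k = the heterogeneity concentration); the individual's
    haploid lineage is then inherited from source 1 with probability
    ``alpha_i``, coupling lineage membership to autosomal ancestry exactly
    as single-parent transmission does in an admixed cohort.
    """

    population_tree: str
    fst: dict[str, float]
    n_per_pop: dict[str, int]
    n_autosomal: int = 2000
    n_haploid: int = 60
    admixture: Admixture | None = None
    private_mutation_rate: float = 0.5
    admixture_heterogeneity: float = 0.0
    #: probability a sample's haploid lineage comes from another population
    #: (a migrant ancestor on the uniparental line)
    migration_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.n_per_pop.values()) < 8:
            raise ValueError("cohort must have at least 8 samples")
        for pop, f in self.fst.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"F for {pop} must be in [0, 1)")
        if self.admixture is not None and all(
            self.fst.get(s, 0.0) == 0.0 for s in self.admixture.sources
        ):
            warnings.warn(
                "admixture requested with F = 0 sources: structure undetectable"
            )

    @property
    def source_pops(self) -> list[str]:
        admixed = {self.admixture.target} if self.admixture else set()
        return [p for p in self.n_per_pop if p not in admixed]

    def sample_ids_for(self, pop: str) -> list[str]:
        return [f"{pop}-{i + 1:03d}" for i in range(self.n_per_pop[pop])]


def default_config(seed: int = 0, scale: float = 1.0) -> DemographyConfig:
    """Five-population cohort (one admixed) mirroring the motivating study.

    ``scale`` shrinks per-population sample counts (minimum 5 each) for
    quick runs without changing the demography.
    """
    base = {"YRI": 53, "CEU": 45, "CHB": 23, "JPT": 23, "AA": 90}
    n = {p: max(8, int(round(c * scale))) for p, c in base.items()}
    # one designated outgroup individual on a long basal lineage branch,
    # autosomally unremarkable, used only to root the parsimony tree
    n = {"OUT": 1, **n}
    return DemographyConfig(
        population_tree=(
            "((((CEU.1:2,CEU.2:2):3,((CHB.1:2,CHB.2:2):2.5,"
            "(JPT.1:2,JPT.2:2):2.5):2.5):3,(YRI.1:2.5,YRI.2:2.5):4):3,OUT:1.5);"
        ),
        fst={"YRI": 0.15, "CEU": 0.12, "CHB": 0.12, "JPT": 0.12, "OUT": 0.15},
        n_per_pop=n,
        admixture=Admixture(target="AA", sources=("YRI", "CEU"), alpha=0.8),
        n_autosomal=2000,
        n_haploid=60,
        private_mutation_rate=0.5,
        admixture_heterogeneity=12.0,
        seed=seed,
    )


def hidden_structure_config(seed: int = 0) -> DemographyConfig:
    """Cohort whose true structure partly hides beyond the scree elbow.

    Two weakly differentiated sub-populations (A1, A2; F = 0.02 each) nest
    inside one apparent population, next to two strongly differentiated
    populations (B, C; F = 0.15).  The visible three-group structure
    dominates the top two components; the A1/A2 split carries little
    variance and surfaces only in a later component — but it is deep in
    the haploid lineage tree, so the phylogenetically guided selection can
    recover it where a scree-based choice cannot.
    """
    return DemographyConfig(
        population_tree="(((A1:3,A2:3):3,C:4):2,B:6);",
        fst={"A1": 0.02, "A2": 0.02, "B": 0.15, "C": 0.15},
        n_per_pop={"B": 30, "C": 30, "A1": 25, "A2": 25},
        n_autosomal=1500,
        n_haploid=100,
        admixture=None,
        private_mutation_rate=0.3,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Shared per-sample assignments (ancestry proportions and lineages)
# ---------------------------------------------------------------------------

def _pop_of(lineage: str) -> str:
    return lineage.split(".")[0]


def _lineages_by_pop(cfg: DemographyConfig) -> dict[str, list[str]]:
    ptree = dendropy.Tree.get(data=cfg.population_tree, schema="newick")
    out: dict[str, list[str]] = {}
    for lf in ptree.leaf_node_iter():
        out.setdefault(_pop_of(lf.taxon.label), []).append(lf.taxon.label)
    return out


def _assignments(cfg: DemographyConfig) -> pd.DataFrame:
    """Per-sample population, ancestry proportion and haploid lineage.

    Drawn from a dedicated random stream so the autosomal and haploid
    simulators agree on each admixed individual's ancestry and on which
    lineage every sample carries.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    lby = _lineages_by_pop(cfg)
    rows = []
    for pop in cfg.n_per_pop:
        for sid in cfg.sample_ids_for(pop):
            if cfg.admixture is not None and pop == cfg.admixture.target:
                s1, s2 = cfg.admixture.sources
                a = cfg.admixture.alpha
                if cfg.admixture_heterogeneity > 0 and 0 < a < 1:
                    k = cfg.admixture_heterogeneity
                    a = float(rng.beta(a * k, (1.0 - a) * k))
                src = s1 if rng.random() < a else s2
                alpha_i = a
            else:
                src, alpha_i = pop, np.nan
            if cfg.migration_rate > 0 and rng.random() < cfg.migration_rate:
                others = [p for p in lby if p != src]
                if others:
                    src = str(rng.choice(others))
            lineage = str(rng.choice(lby[src])) if src in lby else src
            rows.append({"id": sid, "population": pop, "alpha": alpha_i,
                         "source": src, "lineage": lineage})
    return pd.DataFrame(rows).set_index("id")


# ---------------------------------------------------------------------------
# Autosomal genotypes
# ---------------------------------------------------------------------------

def _bn_frequencies(p_anc: np.ndarray, f: float, rng) -> np.ndarray:
    if f == 0.0:
        return p_anc.copy()
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    return np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)


def simulate_autosomal(cfg: DemographyConfig) -> tuple[GenotypeMatrix, pd.Series]:
    """Balding-Nichols diploid genotypes plus true population labels."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    m = cfg.n_autosomal
    p_anc = rng.uniform(0.1, 0.9, size=m)
    pop_freq: dict[str, np.ndarray] = {}
    for pop in cfg.source_pops:
        pop_freq[pop] = _bn_frequencies(p_anc, cfg.fst.get(pop, 0.0), rng)
    assign = _assignments(cfg)

    blocks, ids, labels = [], [], []
    for pop in cfg.n_per_pop:
        n = cfg.n_per_pop[pop]
        pop_ids = cfg.sample_ids_for(pop)
        if cfg.admixture is not None and pop == cfg.admixture.target:
            s1, s2 = cfg.admixture.sources
            alphas = assign.loc[pop_ids, "alpha"].to_numpy()[:, None]
            freqs = alphas * pop_freq[s1] + (1 - alphas) * pop_freq[s2]
            blocks.append(rng.binomial(2, freqs))
        else:
            blocks.append(rng.binomial(2, pop_freq[pop], size=(n, m)))
        ids.extend(pop_ids)
        labels.extend([pop] * n)
    values = np.vstack(blocks).astype(np.int16)

    snp_meta = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(m)],
            "chrom": [str(1 + j % 22) for j in range(m)],
            "pos": np.arange(1, m + 1) * 1000,
            "allele1": "A",
            "allele2": "G",
        }
    )
    sample_meta = pd.DataFrame({"id": ids, "sex": "M", "population": labels})
    g = GenotypeMatrix(values=values, ploidy="diploid", snp_meta=snp_meta,
                       sample_meta=sample_meta)
    return g, pd.Series(labels, index=ids, name="population")


# ---------------------------------------------------------------------------
# Haploid lineage markers
# ---------------------------------------------------------------------------

def simulate_haploid(
    cfg: DemographyConfig, return_sources: bool = False
) -> CharacterMatrix | tuple[CharacterMatrix, pd.Series]:
    """Perfect-phylogeny haploid markers with private-mutation noise.

    With ``return_sources=True`` also returns each sample's lineage source
    population — for admixed samples, the source whose haplotype was
    actually inherited, which is the ground truth for the lineage tree.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    ptree = dendropy.Tree.get(data=cfg.population_tree, schema="newick")
    edges = []
    for nd in ptree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = {lf.taxon.label for lf in nd.leaf_iter()}
        edges.append((below, nd.edge.length or 1.0))
    lineages = {lf.taxon.label for lf in ptree.leaf_node_iter()}
    missing = set(cfg.source_pops) - {_pop_of(l) for l in lineages}
    if missing:
        raise ValueError(f"populations missing from tree: {sorted(missing)}")
    if cfg.n_haploid < len(edges):
        warnings.warn(
            f"{cfg.n_haploid} haploid markers for {len(edges)} branches: "
            "some branches will carry no marker"
        )

    weights = np.array([w for _, w in edges], dtype=float)
    weights = weights / weights.sum()
    marker_edges = rng.choice(len(edges), size=cfg.n_haploid, p=weights)
    lin_haplo = {
        lin: np.array(
            [1 if lin in edges[e][0] else 0 for e in marker_edges], dtype=np.int16
        )
        for lin in lineages
    }

    assign = _assignments(cfg)
    rows, taxa = [], []
    for sid, rec in assign.iterrows():
        hap = lin_haplo[rec["lineage"]].copy()
        k = rng.poisson(cfg.private_mutation_rate)
        if k > 0:
            sites = rng.choice(cfg.n_haploid, size=min(k, cfg.n_haploid),
                               replace=False)
            hap[sites] = 1 - hap[sites]
        rows.append(hap)
        taxa.append(sid)
    chars = CharacterMatrix(taxa=taxa, states=np.array(rows, dtype=np.int16))
    if return_sources:
        return chars, assign["lineage"].rename("lineage")
    return chars


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Everything downstream stages need, with ground truth attached."""

    autosomal: GenotypeMatrix
    haploid: CharacterMatrix
    truth: pd.Series
    config: DemographyConfig
    #: per-sample lineage source (admixed samples: the inherited source pop)
    haploid_truth: pd.Series | None = None

    def suggest_outgroup(self) -> str:
        """A sample of the first non-admixed population whose lineage is
        native to it (the designated outgroup must not be a migrant)."""
        pop = self.config.source_pops[0]
        ids = self.config.sample_ids_for(pop)
        if self.haploid_truth is not None:
            for sid in ids:
                if _pop_of(str(self.haploid_truth[sid])) == pop:
                    return sid
        return ids[0]


def make_cohort(cfg: DemographyConfig) -> CohortBundle:
    """Generate the full synthetic bundle (deterministic per seed)."""
    autosomal, truth = simulate_autosomal(cfg)
    haploid, sources = simulate_haploid(cfg, return_sources=True)
    assert autosomal.sample_ids == haploid.taxa
    return CohortBundle(autosomal=autosomal, haploid=haploid, truth=truth,
                        config=cfg, haploid_truth=sources)


def component_separating(
    scores: PCAResult, truth: pd.Series, group_a: str, group_b: str
) -> int:
    """1-based index of the component best separating two true populations
    (largest |two-sample t| between their score distributions)."""
    ids = scores.sample_ids
    if ids is None:
        raise ValueError("scores must carry sample ids")
    lab = truth.reindex(ids)
    a = np.array(lab == group_a)
    b = np.array(lab == group_b)
    best, best_t = 1, -1.0
    for c in range(1, scores.n_components + 1):
        v = scores.component(c)
        va, vb = v[a], v[b]
        s = np.sqrt(va.var(ddof=1) / a.sum() + vb.var(ddof=1) / b.sum())
        t = abs(va.mean() - vb.mean()) / s if s > 0 else 0.0
        if t > best_t:
            best, best_t = c, t
    return best
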