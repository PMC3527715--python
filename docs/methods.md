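# Methods

`phylopc` implements a phylogenetically guided strategy for choosing which
autosomal principal components (PCs) to include as covariates when
correcting genetic association scans for population stratification. The
guiding idea: mtDNA and Y-chromosome markers are non-recombining and
uniparentally inherited, so a parsimony phylogeny built from them records
population history at a finer grain than the autosomal eigen-spectrum; PCs
that predict membership in well-supported clades of that phylogeny are the
ones that track real population structure, regardless of their eigenvalue
rank.

## Pipeline

1. **PCA** (`structure_pca`). Each autosomal SNP column is mean-centred
   and divided by `sqrt(p(1-p))`, with `p = (1 + Σ g) / (2 + 2n)` over
   non-missing genotypes; missing genotypes are imputed to the
   post-centring mean (0); monomorphic SNPs are dropped. Scores and
   eigenvalues come from the eigendecomposition of the sample-by-sample
   covariance. Score signs are fixed so each column's largest-magnitude
   entry is positive. No outlier removal or LD pruning is applied.

2. **Parsimony phylogeny** (`parsimony_phylo`). The haploid markers are
   binary characters; tree length is the Fitch/Hartigan minimum-change
   score, which is invariant under rerooting and exact on multifurcating
   trees. The search uses random stepwise-addition sequences (greedy
   edge-insertion cost bounds, exact rescoring of complete trees),
   first-improvement NNI hill-climbing, parsimony-ratchet rounds (a random
   quarter of characters temporarily doubled in weight), and optional SPR
   moves. Equally most-parsimonious trees are kept up to a cap (default
   100), deduplicated by unrooted bipartition set, and merged by strict
   consensus. Commercial "drift"/"tree fusing" heuristics are not
   reimplemented; optimality is instead verified against exhaustive
   topology enumeration on small instances in the test suite.

3. **Support, collapse, labels.** Bootstrap support is the percentage of
   character-resampled replicate searches whose strict consensus contains
   a node's bipartition. Nodes with support below 70% or fewer than five
   descendant tips are collapsed. The tree is rooted at the designated
   outgroup's attachment node; since support belongs to bipartitions, not
   nodes, supports are re-keyed by outgroup-free tip set across the
   rerooting. Surviving internal nodes get hierarchical identifiers
   (`X1`, `X2`, `X21`, ...) with children ordered by descending
   descendant count (ties by smallest tip label), so an ancestor's
   identifier is a prefix of its descendants'.

4. **Clade concordance** (`clade_concordance`). For each labelled clade,
   membership is coded binary and regressed on candidate PCs by
   best-subset logistic regression: exhaustive enumeration of the best
   model per size for candidate pools of ≤ 15 components, otherwise a
   forward path ranked by deviance. Model size is chosen by repeated
   stratified 5-fold cross-validation (1,000 replicate partitions by
   default) scored by the Brier score (mean squared difference between
   membership and predicted probability), under a one-standard-error
   rule: the smallest size whose mean error is within one standard error
   of the best size's mean (`SubsetCVConfig.band="se"`; the raw
   replicate standard deviation is available as `band="sd"` and is much
   more conservative). Selected components are refit in one multiple
   logistic regression for per-component beta, SE and Wald p-values;
   complete separation — routine when clades coincide with well
   differentiated populations — triggers a Firth-penalised refit (step
   halving on the penalised likelihood), with a ridge-stabilised fit as a
   final fallback, and flags the affected cells. A clade whose smaller
   membership class has fewer samples than the number of folds cannot be
   cross-validated and is skipped with a warning.

5. **Selection** counts, per component, the number of clades whose model
   includes it, then keeps components whose count reaches a cutoff. The
   packaged transcription of the published 10-clade association table
   reproduces the published sets: cutoff 5 gives components
   {1, 2, 33, 34} and cutoff 3 gives {1, 2, 4, 5, 33, 34, 35}.

6. **Type I error** (`null_trait_sim`, `type1_eval`). Null phenotypes are
   evolved by Brownian motion (root 0; per-branch change
   `Normal(0, rate × length)`, rate 1) on each equally most-parsimonious
   tree — unit branch lengths on cladograms — 15 replicates per tree, so
   seven trees give 105 datasets. Each dataset is scanned by per-SNP OLS
   (traits are continuous) with each strategy's PCs as covariates,
   implemented by projecting traits and genotypes off the covariate space
   (Frisch–Waugh), which reproduces the full-model genotype t-test
   exactly. Calibration is summarised by the null-proportion statistic
   `eta = #{p > 0.5} / (m/2)` truncated to [0, 1], by counts of Storey
   q-values below 0.20 (with `pi0` set to `eta`), and by counts of
   Benjamini–Hochberg adjusted p-values below 0.20 (a Grenander-density
   local-fdr is available separately). Medians of the per-dataset counts
   compare strategies; no formal test is attempted because the datasets
   share trees.

## Synthetic cohorts

The generator (`synth_cohort`) emulates the study design the method
targets. Autosomal genotypes follow the Balding–Nichols model: per-SNP
ancestral frequency `Uniform(0.1, 0.9)`; per-population frequency
`Beta(p(1-F)/F, (1-p)(1-F)/F)`; genotypes `Binomial(2, p_pop)`.
Haploid lineages are tips of a small population-lineage tree; each marker
mutates 0→1 on one branch chosen in proportion to branch length, samples
inherit their lineage's root-to-tip mutation set, and Poisson-many private
flips per sample (rate 0.5 by default) add homoplasy. Lineage structure is
deliberately finer than autosomal structure — two lineages per population
in the default demography — because that asymmetry is precisely what makes
uniparental markers informative.

Admixed individuals draw a personal ancestry proportion
`alpha_i ~ Beta(alpha·k, (1-alpha)·k)` (k = `admixture_heterogeneity`,
default 12 in the default cohort) that governs both their autosomal
mixture frequency and, via single-parent transmission, which source
population's lineage they carry. An optional `migration_rate` gives any
sample a small probability of carrying another population's lineage — the
migrant-male scenario — which makes clade membership imperfectly
predictable from PCs, as in real cohorts. One designated outgroup
individual sits on its own basal lineage branch and is autosomally
unremarkable; it exists to root the tree, mirroring the use of a
designated outgroup sample in the motivating study.

Two stock configurations:

* `default_config` — five populations (four reference groups scaled from
  53/45/23/23 plus 90 admixed individuals at alpha = 0.8), 2,000
  autosomal and 60 haploid SNPs; a `scale` argument shrinks sample counts
  proportionally.
* `hidden_structure_config` — populations B and C at F = 0.15 beside one
  apparent population split into sub-populations A1/A2 at F = 0.02, with
  110 samples, 1,500 autosomal and 100 haploid markers. The A1/A2 axis
  carries so little variance that it surfaces only beyond the scree
  elbow, yet the split is deep and well supported in the lineage tree —
  the situation the method exists for.

What the generator does **not** emulate: linkage disequilibrium,
recombination maps, realistic site-frequency spectra, genotyping error,
or coalescent noise within populations. Passing tests therefore show that
the method behaves as described when its premise holds (lineage signal
concordant with, and finer than, autosomal structure), not that the
premise holds in any particular real cohort.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale versions of the study
conditions chosen to keep full runs in minutes: searches use 2–3 random
addition sequences with 1–2 ratchet rounds, bootstraps use 25 replicates,
and cross-validation uses 20–50 replicate partitions (the library
defaults remain 1,000 bootstrap replicates and 1,000 CV partitions). The
five-population recovery analysis uses half-scale population counts with
1,500 autosomal and 120 haploid markers and a 6% lineage migration rate;
component selection there uses an absolute count cutoff of 3, matching
the published cutoff-to-clade-count ratio rather than scaling the cutoff
with the clade count. Monte-Carlo moment checks of the trait simulator
use 10,000 replicates with 5% tolerance.

Other numerical details: the CV inner loop uses a Newton/IRLS logistic
fit with a 10⁻⁶ ridge so separated folds stay finite (far below the scale
of any real effect); deviance ties in the subset path resolve to the
lowest component index; equal-length trees are deduplicated by canonical
bipartition set; per-stage seeds are derived from one master seed via a
seed sequence, so every output is reproducible byte-for-byte from the
manifest.

## Known limitations

* The search is heuristic; on large, homoplasy-rich matrices the set of
  equally most-parsimonious trees is capped and the strict consensus can
  over-resolve relative to the full tie set.
* The one-standard-error band often admits one incidental component
  alongside the truly predictive ones (visible as weak singleton entries
  in the published table as well); selection cutoffs ≥ 2 absorb this.
* Bootstrap support uses one addition sequence per replicate by default
  and slightly underestimates support on hard replicates.
* `eta` uses the λ = 0.5 threshold estimator; other null-proportion
  estimators would shift q-value counts slightly.
* With very small clades (smaller class < number of folds) the
  concordance step has no defensible cross-validation and skips the
  clade rather than guessing.
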