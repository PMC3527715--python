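"""Concordance of haploid-lineage clades with autosomal principal components.

For every retained clade of the collapsed parsimony tree, membership
(inside/outside) is coded binary and regressed on candidate principal
components by best-subset logistic regression.  Candidate models are the
best model of each size (exhaustive enumeration for small candidate pools,
otherwise a forward-selection path ranked by logistic deviance).  Model
size is chosen by repeated k-fold cross-validation under the
one-standard-error rule: the smallest model whose mean held-out Brier
score (mean squared difference between membership and predicted
probability) is within one standard deviation — across the replicate fold
partitions — of the best model's mean error.  The selected components are
then refit in a single multiple logistic regression to report beta, SE and
Wald p-value per component, falling back to a Firth-penalised fit when the
clade is perfectly separated in component space (common for well
differentiated populations).

Counting how often each component is selected across clades, and keeping
the components whose count reaches a cutoff, yields the phylogenetically
guided covariate set used for stratification correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .core_io import AssociationCell, CladeAssociationTable, PhyloTree
from .structure_pca import PCAResult

__all__ = [
    "SubsetCVConfig",
    "SelectionResult",
    "clade_membership",
    "best_subset_cv",
    "refit_logistic",
    "build_association_table",
    "count_components",
    "select_components",
]

log = logging.getLogger(__name__)


@dataclass
class SubsetCVConfig:
    """Settings for the best-subset cross-validation procedure."""

    n_folds: int = 5
    n_replicates: int = 1000
    max_model_size: int = 15
    candidate_components: list[int] = field(
        default_factory=lambda: list(range(1, 51))
    )
    seed: int = 0
    #: exhaustive best-subset enumeration; None = automatic (pools of <= 15)
    exhaustive: bool | None = None
    #: width of the parsimony band around the best CV error: "se" uses the
    #: standard error of the mean error across replicate partitions (the
    #: cited one-standard-error rule applied to the replicate-CV estimate),
    #: "sd" the raw replicate standard deviation (much more conservative)
    band: str = "se"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.max_model_size > len(self.candidate_components):
            raise ValueError("max_model_size exceeds candidate pool")


@dataclass
class SelectionResult:
    """Cross-clade component counts and the cutoff-selected set."""

    counts: dict[int, int]
    cutoff: int
    chosen: list[int]


# ---------------------------------------------------------------------------
# Clade membership
# ---------------------------------------------------------------------------

def clade_membership(tree: PhyloTree, clade_id: str, samples: list[str]) -> np.ndarray:
    """Binary vector: 1 for samples that are tips inside the clade."""
    members = set(tree.clade_tips(clade_id))
    tipset = set(tree.tip_labels)
    unknown = [s for s in samples if s not in tipset]
    if unknown:
        raise ValueError(f"samples not in tree: {unknown[:5]}")
    return np.array([1 if s in members else 0 for s in samples], dtype=np.int8)


# ---------------------------------------------------------------------------
# Lightweight ridge-stabilised logistic fits (used inside the CV loop)
# ---------------------------------------------------------------------------

def _fit_logit(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
               max_iter: int = 30, tol: float = 1e-8):
    """Newton/IRLS logistic fit with a tiny ridge for numerical safety.

    Returns (beta, deviance).  The ridge keeps separated fits finite; it is
    far below the scale of any real effect and irrelevant for model ranking.
    """
    n, p = X.shape
    beta = np.zeros(p)
    eye = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu) + 1e-12
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X.T * w) @ X + ridge * eye
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35))), 1e-12, 1 - 1e-12)
    dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return beta, dev


def _predict(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -35, 35)))


def _design(scores: PCAResult, comps: tuple[int, ...], rows=None) -> np.ndarray:
    cols = [np.ones(scores.scores.shape[0])] + [scores.component(c) for c in comps]
    X = np.column_stack(cols)
    return X if rows is None else X[rows]


# ---------------------------------------------------------------------------
# Best-subset path + cross-validated size selection
# ---------------------------------------------------------------------------

def _candidate_path(y, scores, candidates, max_size, exhaustive):
    """Best component set of each size 0..max_size, ranked by deviance."""
    path: list[tuple[int, ...]] = [()]
    if exhaustive:
        for size in range(1, max_size + 1):
            best, best_dev = None, math.inf
            for comb in itertools.combinations(candidates, size):
                _, dev = _fit_logit(_design(scores, comb), y)
                if dev < best_dev - 1e-12:
                    best, best_dev = comb, dev
            path.append(best)
    else:
        current: tuple[int, ...] = ()
        for _ in range(max_size):
            best, best_dev = None, math.inf
            for c in candidates:
                if c in current:
                    continue
                comb = current + (c,)
                _, dev = _fit_logit(_design(scores, comb), y)
                if dev < best_dev - 1e-12:
                    best, best_dev = comb, dev
            current = best
            path.append(current)
    return path


def best_subset_cv(y: np.ndarray, scores: PCAResult, cfg: SubsetCVConfig) -> list[int]:
    """Select components predicting clade membership, by the 1-SD CV rule.

    Returns the (ascending) component set of the chosen model size; an
    empty list when the intercept-only model already performs within one
    standard deviation of the best.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n != scores.scores.shape[0]:
        raise ValueError("membership vector and scores have different lengths")
    if y.min() == y.max():
        raise ValueError("degenerate clade: only one membership class present")
    candidates = [c for c in cfg.candidate_components if c <= scores.n_components]
    if len(candidates) < len(cfg.candidate_components):
        log.info(
            "restricting candidates to %d available components", len(candidates)
        )
    max_size = min(cfg.max_model_size, len(candidates), n - 2)
    exhaustive = (
        cfg.exhaustive if cfg.exhaustive is not None else len(candidates) <= 15
    )
    path = _candidate_path(y, scores, candidates, max_size, exhaustive)
    designs = [_design(scores, comps) for comps in path]

    import warnings as _warnings

    rng = np.random.default_rng(cfg.seed)
    errors = np.empty((cfg.n_replicates, len(path)))
    for r in range(cfg.n_replicates):
        kf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                             random_state=int(rng.integers(2**31)))
        sq = np.zeros(len(path))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            folds = list(kf.split(y, y))
        for train, test in folds:
            ytr = y[train]
            for s, X in enumerate(designs):
                beta, _ = _fit_logit(X[train], ytr)
                pred = _predict(X[test], beta)
                sq[s] += float(np.sum((y[test] - pred) ** 2))
        errors[r] = sq / n
    mean_err = errors.mean(axis=0)
    s_star = int(np.argmin(mean_err))
    band = float(errors[:, s_star].std(ddof=1)) if cfg.n_replicates > 1 else 0.0
    if cfg.band == "se":
        band /= math.sqrt(cfg.n_replicates)
    elif cfg.band != "sd":
        raise ValueError(f"unknown band rule {cfg.band!r}")
    chosen_size = next(
        s for s in range(len(path)) if mean_err[s] <= mean_err[s_star] + band
    )
    return sorted(path[chosen_size])


# ---------------------------------------------------------------------------
# Refit of the selected model
# ---------------------------------------------------------------------------

def _firth_penalized_loglik(X, y, beta):
    mu = np.clip(_predict(X, beta), 1e-12, 1 - 1e-12)
    w = mu * (1.0 - mu) + 1e-12
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    sign, logdet = np.linalg.slogdet((X.T * w) @ X)
    return ll + 0.5 * (logdet if sign > 0 else -np.inf)


def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 150,
               tol: float = 1e-7):
    """Firth-penalised logistic regression (Jeffreys-prior bias reduction)
    with step halving, so separated designs converge to finite estimates."""
    n, p = X.shape
    beta = np.zeros(p)
    pll = _firth_penalized_loglik(X, y, beta)
    for _ in range(max_iter):
        mu = _predict(X, beta)
        w = mu * (1.0 - mu) + 1e-12
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        if not np.all(np.isfinite(step)):
            raise RuntimeError("Firth fit diverged")
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        new_beta, new_pll = beta, -np.inf
        for _half in range(12):
            cand = beta + step
            cand_pll = _firth_penalized_loglik(X, y, cand)
            if cand_pll >= pll - 1e-12:
                new_beta, new_pll = cand, cand_pll
                break
            step = step / 2.0
        else:
            return _finish_firth(X, y, beta)  # no uphill step left
        converged = np.max(np.abs(new_beta - beta)) < tol
        beta, pll = new_beta, new_pll
        if converged:
            break
    return _finish_firth(X, y, beta)


def _finish_firth(X, y, beta):
    mu = _predict(X, beta)
    w = mu * (1.0 - mu) + 1e-12
    cov = np.linalg.pinv((X.T * w) @ X)
    se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    return beta, se


def refit_logistic(
    y: np.ndarray, scores: PCAResult, selected: list[int]
) -> dict[int, AssociationCell]:
    """Multiple logistic regression of membership on the selected components.

    Reports per-component beta, SE and two-sided Wald p-value.  When the
    maximum-likelihood fit shows complete separation (non-finite or wildly
    diverging estimates), a Firth-penalised fit is substituted and the
    affected cells are flagged.
    """
    import statsmodels.api as sm

    if not selected:
        raise ValueError("selected component set is empty")
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("degenerate clade: only one membership class present")
    X = _design(scores, tuple(selected))

    separated = False
    beta = se = None
    try:
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta, se = fit.params, fit.bse
        if (not np.all(np.isfinite(se))) or np.max(np.abs(beta)) > 30:
            separated = True
    except Exception:
        separated = True
    if separated:
        try:
            beta, se = _firth_fit(X, y)
        except (RuntimeError, np.linalg.LinAlgError):
            # last resort: ridge-stabilised fit with observed-information
            # standard errors; estimates are finite but approximate
            log.warning(
                "Firth refit failed for components %s; reporting "
                "ridge-stabilised estimates", selected,
            )
            beta, _ = _fit_logit(X, y, ridge=1e-4)
            mu = _predict(X, beta)
            w = mu * (1.0 - mu) + 1e-12
            cov = np.linalg.pinv((X.T * w) @ X + 1e-4 * np.eye(X.shape[1]))
            se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))

    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    out: dict[int, AssociationCell] = {}
    for j, comp in enumerate(selected, start=1):
        out[comp] = AssociationCell(
            p=float(max(pvals[j], np.finfo(float).tiny)),
            beta=float(beta[j]),
            se=float(se[j]),
            separation=separated,
        )
    return out


# ---------------------------------------------------------------------------
# Table assembly and cutoff selection
# ---------------------------------------------------------------------------

def build_association_table(
    tree: PhyloTree, scores: PCAResult, cfg: SubsetCVConfig
) -> CladeAssociationTable:
    """Run the subset procedure for every labelled clade of the tree."""
    samples = scores.sample_ids
    if samples is None:
        raise ValueError("scores must carry sample ids")
    clade_ids = sorted(tree.clades)
    table = CladeAssociationTable(
        clades=clade_ids,
        components=[c for c in cfg.candidate_components],
        cells={},
    )
    rng = np.random.default_rng(cfg.seed)
    for clade in clade_ids:
        y = clade_membership(tree, clade, samples)
        smaller = int(min(y.sum(), len(y) - y.sum()))
        if smaller < cfg.n_folds:
            log.warning(
                "skipping clade %s: smaller membership class has %d samples "
                "(< %d folds)", clade, smaller, cfg.n_folds,
            )
            continue
        sub_cfg = SubsetCVConfig(
            n_folds=cfg.n_folds,
            n_replicates=cfg.n_replicates,
            max_model_size=cfg.max_model_size,
            candidate_components=list(cfg.candidate_components),
            seed=int(rng.integers(2**31)),
            exhaustive=cfg.exhaustive,
            band=cfg.band,
        )
        try:
            selected = best_subset_cv(y, scores, sub_cfg)
            if selected:
                cells = refit_logistic(y, scores, selected)
                for comp, cell in cells.items():
                    table.cells[(clade, comp)] = cell
        except (ValueError, RuntimeError) as exc:
            log.warning("skipping clade %s: %s", clade, exc)
    return table


def count_components(t: CladeAssociationTable) -> dict[int, int]:
    """Number of clades for which each component was selected."""
    return t.counts()


def select_components(counts: dict[int, int], cutoff: int) -> list[int]:
    """Ascending list of components selected in at least ``cutoff`` clades."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    return sorted(c for c, k in counts.items() if k >= cutoff)
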