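"""Per-SNP association scans on null phenotypes and Type I error metrics.

Each simulated trait is regressed on every SNP by ordinary least squares
with the correction strategy's principal components as covariates (the
traits are continuous, so the scan is linear); the two-sided p-value for
the genotype coefficient is recorded per SNP.  Calibration of a strategy
is then summarised three ways, per simulated dataset:

* the null-proportion statistic ``eta`` — the fraction of p-values above
  0.5 divided by its uniform expectation, truncated to [0, 1]; values near
  1 indicate the p-values are consistent with a uniform null;
* the number of SNPs with Storey q-value below a threshold (0.20 by
  default), with the null proportion estimated by ``eta``;
* the number of SNPs with Benjamini-Hochberg adjusted p-value below the
  same threshold.

Because every trait is null by construction, any SNP passing either
threshold is a false positive; medians of the per-dataset counts compare
correction strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import MISSING, GenotypeMatrix
from .null_trait_sim import TraitDataset
from .structure_pca import PCAResult

__all__ = [
    "CorrectionStrategy",
    "ScanResult",
    "EvalReport",
    "snp_scan",
    "eta_statistic",
    "q_values",
    "fdr_adjust",
    "evaluate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionStrategy:
    """A named set of principal components used as scan covariates."""

    name: str
    covariate_components: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        comps = tuple(self.covariate_components)
        if len(set(comps)) != len(comps) or any(c < 1 for c in comps):
            raise ValueError("covariate components must be unique and >= 1")
        object.__setattr__(self, "covariate_components", comps)


@dataclass
class ScanResult:
    """Per-SNP p-values with a mask of degenerate (monomorphic) tests."""

    pvals: np.ndarray
    degenerate: np.ndarray


# ---------------------------------------------------------------------------
# Scan machinery
# ---------------------------------------------------------------------------

def _prepare_genotypes(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing genotypes; return (matrix, monomorphic mask)."""
    G = g.values.astype(float)
    miss = g.values == MISSING
    if miss.any():
        with np.errstate(invalid="ignore"):
            col_mean = np.where(
                (~miss).sum(axis=0) > 0,
                np.nansum(np.where(miss, np.nan, G), axis=0)
                / np.maximum((~miss).sum(axis=0), 1),
                0.0,
            )
        G[miss] = np.broadcast_to(col_mean, G.shape)[miss]
    mono = G.std(axis=0) == 0
    return G, mono


def _covariate_basis(scores: PCAResult, comps: tuple[int, ...], n: int) -> np.ndarray:
    cols = [np.ones(n)]
    for c in comps:
        cols.append(scores.component(c))
    X = np.column_stack(cols)
    q, _ = np.linalg.qr(X)
    return q


def _scan_matrix(Y: np.ndarray, G: np.ndarray, mono: np.ndarray,
                 q_basis: np.ndarray) -> np.ndarray:
    """OLS genotype p-values for all traits at once.

    ``Y`` is samples x traits, ``G`` samples x SNPs.  Traits and genotypes
    are projected off the covariate space (Frisch-Waugh), so the t-test on
    the residual regression equals the full-model genotype t-test with
    ``df = n - n_covariates - 2``.
    """
    n, m = G.shape
    k = q_basis.shape[1]  # includes intercept
    df = n - k - 1
    if df < 1:
        raise ValueError("not enough samples for the covariate set")
    rY = Y - q_basis @ (q_basis.T @ Y)
    rG = G - q_basis @ (q_basis.T @ G)
    gg = np.einsum("ij,ij->j", rG, rG)
    yy = np.einsum("ij,ij->j", rY, rY)
    gy = rG.T @ rY  # m x d
    ok = gg > n * np.finfo(float).eps
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok[:, None], gy / gg[:, None], 0.0)
        rss = yy[:, None] - beta.T**2 * gg[None, :]
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg[None, :])
        t = np.where((se > 0) & ok[None, :], beta.T / se, 0.0)
    pv = 2.0 * stats.t.sf(np.abs(t), df)
    pv[:, ~ok] = 1.0
    pv[:, mono] = 1.0
    return pv


def snp_scan(
    trait: TraitDataset,
    g: GenotypeMatrix,
    scores: PCAResult,
    strategy: CorrectionStrategy,
) -> ScanResult:
    """Linear association scan of one null trait against every SNP."""
    ids = g.sample_ids
    if scores.sample_ids is not None and scores.sample_ids != ids:
        bad = [a for a, b in zip(scores.sample_ids, ids) if a != b][:5]
        raise ValueError(f"sample order mismatch between scores and genotypes: {bad}")
    missing_ids = [s for s in ids if s not in trait.values]
    if missing_ids:
        raise ValueError(f"trait lacks values for samples: {missing_ids[:5]}")
    y = trait.vector(ids)

    G, mono = _prepare_genotypes(g)
    qb = _covariate_basis(scores, strategy.covariate_components, len(ids))
    if np.var(y) == 0:
        return ScanResult(
            pvals=np.ones(g.n_snps), degenerate=np.ones(g.n_snps, dtype=bool)
        )
    pv = _scan_matrix(y[:, None], G, mono, qb)[0]
    return ScanResult(pvals=pv, degenerate=mono.copy())


# ---------------------------------------------------------------------------
# Uniformity and FDR machinery
# ---------------------------------------------------------------------------

def eta_statistic(pvals: np.ndarray, lam: float = 0.5) -> float:
    """Estimated null proportion: ``#{p > lam} / (m (1 - lam))`` in [0, 1]."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    eta = (p > lam).sum() / (p.size * (1.0 - lam))
    return float(min(max(eta, 0.0), 1.0))


def q_values(pvals: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with the null proportion estimated by ``eta``.

    ``q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j`` over the sorted
    p-values, clipped to [0, 1]; monotone non-decreasing in p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if pi0 is None:
        pi0 = eta_statistic(p)
        if pi0 == 0.0:
            pi0 = 1.0 / p.size  # degenerate: no p-values above lambda
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def local_fdr(pvals: np.ndarray) -> np.ndarray:
    """Density-based local false discovery rate (Grenander estimator).

    Offered as an alternative to the step-up adjustment: the p-value
    density is estimated by the Grenander (decreasing) estimator and the
    local fdr is ``pi0 / f(p)`` clipped to [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    pi0 = eta_statistic(p)
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    # empirical CDF points, then least concave majorant slopes
    x = np.concatenate([[0.0], ps, [1.0]])
    yv = np.concatenate([[0.0], np.arange(1, m + 1) / m, [1.0]])
    slopes = np.zeros(m)
    hull_x, hull_y = [0.0], [0.0]
    for xi, yi in zip(x[1:], yv[1:]):
        hull_x.append(xi)
        hull_y.append(yi)
        while len(hull_x) >= 3:
            s1 = (hull_y[-1] - hull_y[-2]) / max(hull_x[-1] - hull_x[-2], 1e-300)
            s0 = (hull_y[-2] - hull_y[-3]) / max(hull_x[-2] - hull_x[-3], 1e-300)
            if s1 >= s0:
                hull_x.pop(-2)
                hull_y.pop(-2)
            else:
                break
    dens = np.ones(m)
    seg = 0
    for i, pi in enumerate(ps):
        while seg + 1 < len(hull_x) - 1 and hull_x[seg + 1] < pi:
            seg += 1
        dx = hull_x[seg + 1] - hull_x[seg]
        dy = hull_y[seg + 1] - hull_y[seg]
        dens[i] = dy / max(dx, 1e-300)
    out = np.empty(m)
    out[order] = np.clip(pi0 / np.maximum(dens, 1e-300), 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Strategy comparison
# ---------------------------------------------------------------------------

@dataclass
class StrategyEval:
    """Calibration summary of one correction strategy over all datasets."""

    name: str
    eta: list[float] = field(default_factory=list)
    q_counts: list[int] = field(default_factory=list)
    fdr_counts: list[int] = field(default_factory=list)

    @property
    def median_eta(self) -> float:
        return float(np.median(self.eta))

    @property
    def median_q_count(self) -> float:
        return float(np.median(self.q_counts))

    @property
    def median_fdr_count(self) -> float:
        return float(np.median(self.fdr_counts))


@dataclass
class EvalReport:
    """Per-strategy Type I error summaries over a batch of null datasets."""

    strategies: dict[str, StrategyEval]
    threshold: float
    n_datasets: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, ev in self.strategies.items():
            rows.append(
                {
                    "strategy": name,
                    "median_eta": ev.median_eta,
                    "median_q_fp": ev.median_q_count,
                    "median_fdr_fp": ev.median_fdr_count,
                    "total_q_fp": int(np.sum(ev.q_counts)),
                    "total_fdr_fp": int(np.sum(ev.fdr_counts)),
                }
            )
        return pd.DataFrame(rows)


def evaluate(
    strategies: list[CorrectionStrategy],
    traits: list[TraitDataset],
    g: GenotypeMatrix,
    scores: PCAResult,
    threshold: float = 0.20,
) -> EvalReport:
    """Scan every dataset under every strategy; summarise false positives.

    For each dataset and strategy the scan p-values give an ``eta``
    statistic and counts of SNPs with q-value / BH-adjusted value below the
    threshold; counts are pooled into per-strategy medians.  No
    significance test is attempted across strategies — the datasets share
    trees and are not independent.
    """
    if not strategies or not traits:
        raise ValueError("need at least one strategy and one dataset")
    ids = g.sample_ids
    Y = np.column_stack([t.vector(ids) for t in traits])
    G, mono = _prepare_genotypes(g)

    report = EvalReport(strategies={}, threshold=threshold, n_datasets=len(traits))
    for strat in strategies:
        qb = _covariate_basis(scores, strat.covariate_components, len(ids))
        pmat = _scan_matrix(Y, G, mono, qb)
        ev = StrategyEval(name=strat.name)
        for d in range(pmat.shape[0]):
            pv = pmat[d]
            ev.eta.append(eta_statistic(pv))
            ev.q_counts.append(int((q_values(pv) < threshold).sum()))
            ev.fdr_counts.append(int((fdr_adjust(pv) < threshold).sum()))
        report.strategies[strat.name] = ev
    return report
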