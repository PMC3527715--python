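"""Eigenstrat-style principal-component analysis of autosomal genotypes.

Each SNP column is mean-centred and divided by the binomial standard
deviation ``sqrt(p(1-p))`` where ``p`` is a posterior allele-frequency
estimate ``(1 + sum_i g_ij) / (2 + 2 n_j)`` over the ``n_j`` non-missing
genotypes; missing genotypes are imputed to the column mean (0 after
centring).  Sample scores and eigenvalues come from the sample-by-sample
covariance of the normalised matrix.  Components are ordered by descending
eigenvalue, and each score column's sign is fixed so its largest-magnitude
entry is positive, making results stable across eigensolvers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import MISSING, GenotypeMatrix

__all__ = ["PCAResult", "normalize_genotypes", "compute_pcs", "scree", "run_pca"]

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Principal-component scores and eigenvalues.

    ``scores`` is samples x K with columns ordered by descending
    eigenvalue; component indices are 1-based throughout the package.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    n_snps_used: int
    sample_ids: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def component(self, index: int) -> np.ndarray:
        """Score vector for a 1-based component index."""
        if not 1 <= index <= self.n_components:
            raise IndexError(f"component {index} outside 1..{self.n_components}")
        return self.scores[:, index - 1]

    def to_frame(self):
        import pandas as pd

        ids = self.sample_ids or [f"S{i}" for i in range(self.scores.shape[0])]
        cols = {f"PC{k + 1}": self.scores[:, k] for k in range(self.n_components)}
        return pd.DataFrame({"id": ids, **cols})


def normalize_genotypes(g: GenotypeMatrix) -> np.ndarray:
    """Centre and scale a diploid genotype matrix, SNP by SNP.

    Monomorphic SNPs (no variation among non-missing genotypes) carry no
    structure information and are dropped; missing entries become 0 after
    centring (mean imputation).
    """
    if g.ploidy != "diploid":
        raise ValueError("PCA normalisation expects a diploid matrix")
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    vals = g.values.astype(float)
    miss = g.values == MISSING
    vals[miss] = np.nan

    n_obs = (~miss).sum(axis=0)
    totals = np.nansum(vals, axis=0)
    with np.errstate(invalid="ignore"):
        mean = totals / np.maximum(n_obs, 1)
        var = np.nanvar(vals, axis=0)
    poly = (n_obs >= 2) & (var > 0)
    n_dropped = int((~poly).sum())
    if not poly.any():
        raise ValueError("no informative SNPs (all columns monomorphic)")
    if n_dropped:
        log.info("dropped %d monomorphic/unobserved SNPs", n_dropped)

    vals = vals[:, poly]
    mean = mean[poly]
    p_hat = (1.0 + totals[poly]) / (2.0 + 2.0 * n_obs[poly])
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    out = (vals - mean) / scale
    out[np.isnan(out)] = 0.0
    return out


def compute_pcs(m: np.ndarray, k: int) -> PCAResult:
    """Eigendecompose the sample-by-sample covariance of a normalised matrix.

    Returns the top ``k`` components (truncated to the matrix rank, with a
    warning, if ``k`` exceeds it).
    """
    n, p = m.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(samples-1, SNPs)={min(n - 1, p)}")
    cov = (m @ m.T) / p
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    rank = int((evals > max(n, p) * np.finfo(float).eps * max(evals[0], 1.0)).sum())
    if k > rank:
        log.warning("requested %d components but rank is %d; truncating", k, rank)
        k = rank
    evals = np.clip(evals[:k], 0.0, None)
    scores = evecs[:, :k] * np.sqrt(np.clip(evals, 0, None) * n)

    # deterministic sign: largest-magnitude entry of each column positive
    for j in range(scores.shape[1]):
        col = scores[:, j]
        if col.any():
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                scores[:, j] = -col
    return PCAResult(scores=scores, eigenvalues=evals, n_snps_used=p)


def scree(r: PCAResult, n: int = 50) -> list[tuple[int, float]]:
    """First ``n`` (1-based component, eigenvalue) pairs, eigenvalues
    non-increasing."""
    if n > r.n_components:
        raise ValueError(f"n={n} exceeds available components {r.n_components}")
    return [(i + 1, float(r.eigenvalues[i])) for i in range(n)]


def run_pca(g: GenotypeMatrix, k: int) -> PCAResult:
    """Normalise and decompose in one step, keeping sample ids attached."""
    m = normalize_genotypes(g)
    k = min(k, g.n_samples - 1, m.shape[1])
    res = compute_pcs(m, k)
    res.sample_ids = g.sample_ids
    return res
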