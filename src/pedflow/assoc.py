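"""Candidate-SNP association (PCA + kinship mixed model) and trait tests.

The association model for a candidate marker is the single-variance-
component mixed model

    y = mu + PCs * beta + marker * alpha + u + e,   u ~ N(0, sg^2 K)

with K a VanRaden genomic relationship matrix and the leading genotype
principal components as fixed covariates.  The variance ratio is estimated
once under the null via the eigendecomposition of K and reused for every
marker (P3D); each marker is then tested by generalized least squares with a
Wald test.  With K = I and no PCs this collapses exactly to ordinary
least-squares marker regression.

Group phenotype comparisons follow the classical two-stage recipe: an F test
of variance equality at 0.05 chooses between the pooled and the
unequal-variance (Welch) two-sample t test, two-sided, with significance
stars at 0.05 and 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .vcfio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KinshipMatrix",
    "AssociationResult",
    "kinship_matrix",
    "genotype_pca",
    "mlm_scan",
    "group_phenotype_test",
    "derive_yield_traits",
    "phenotype_means",
]


@dataclass
class KinshipMatrix:
    samples: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape mismatch")


@dataclass(frozen=True)
class AssociationResult:
    site_id: str
    effect: float
    stderr: float
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value))


def _imputed_dosages(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(mean-imputed dosage matrix, per-site alt frequency p)."""
    X = gm.codes.astype(float)
    X[X == MISSING] = np.nan
    means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), means, X)
    return X, means / 2.0


def kinship_matrix(gm: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship: centered cross-product / sum 2p(1-p).

    Missing dosages are imputed to the site mean; sites fixed after
    filtering (p of 0 or 1) carry no information and are excluded.
    """
    X, p = _imputed_dosages(gm)
    keep = (p > 0) & (p < 1)
    X, p = X[:, keep], p[keep]
    Z = X - 2 * p
    denom = float(np.sum(2 * p * (1 - p)))
    if denom == 0:
        raise ValueError("no polymorphic sites for kinship")
    return KinshipMatrix(list(gm.samples), Z @ Z.T / denom)


def genotype_pca(gm: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Sample scores of the top-k genotype principal components.

    Eigendecomposition of the covariance of mean-imputed, centered dosages;
    components ordered by descending eigenvalue; each component's sign is
    fixed by making its largest-magnitude loading positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if gm.n_samples <= k:
        raise ValueError("need more samples than components")
    X, _ = _imputed_dosages(gm)
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for c in range(min(k, vt.shape[0])):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            scores[:, c] *= -1.0
    return scores


def _null_reml_delta(y: np.ndarray, X0: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Estimate delta = se^2/sg^2 under the null model by ML on the rotated data.

    Returns (eigenvalues of K, eigenvector matrix, delta).
    """
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X0
    n = len(y)

    def neg_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        v = w + delta
        Wv = Xr / v[:, None]
        xtx = Xr.T @ Wv
        beta = np.linalg.solve(xtx, Wv.T @ yr)
        resid = yr - Xr @ beta
        sg2 = float(resid @ (resid / v)) / n
        return 0.5 * (n * np.log(2 * np.pi * sg2) + np.sum(np.log(v)) + n)

    res = optimize.minimize_scalar(neg_ll, bounds=(-10.0, 10.0), method="bounded")
    return w, U, float(np.exp(res.x))


def mlm_scan(
    phenotype: np.ndarray,
    gm: GenotypeMatrix,
    pcs: Optional[np.ndarray] = None,
    K: Optional[KinshipMatrix] = None,
    site_ids: Optional[Sequence[str]] = None,
    per_marker_reml: bool = False,
) -> list[AssociationResult]:
    """Mixed-model association of each candidate site with a phenotype.

    ``phenotype`` must align with ``gm.samples``.  Monomorphic markers are
    skipped with a log entry.  With ``per_marker_reml`` the variance ratio is
    re-estimated for every marker instead of once under the null.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n != gm.n_samples:
        raise ValueError("phenotype and genotype samples misaligned")
    X0_parts = [np.ones((n, 1))]
    if pcs is not None and pcs.size:
        X0_parts.append(np.asarray(pcs, dtype=float))
    X0 = np.hstack(X0_parts)
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("singular fixed-effect design")
    Kv = K.values if K is not None else np.eye(n)

    w, U, delta = _null_reml_delta(y, X0, Kv)
    yr = U.T @ y
    X0r = U.T @ X0
    ids = list(site_ids) if site_ids is not None else list(gm.site_ids())
    Xall, _ = _imputed_dosages(gm)

    results: list[AssociationResult] = []
    for j in range(gm.n_sites):
        x = Xall[:, j]
        if np.std(x) == 0:
            logger.info("marker %s monomorphic; skipped", ids[j])
            continue
        if per_marker_reml:
            wj, Uj, dj = _null_reml_delta(y, np.hstack([X0, x[:, None]]), Kv)
            vr = wj + dj
            Xr = Uj.T @ np.hstack([X0, x[:, None]])
            yrj = Uj.T @ y
        else:
            vr = w + delta
            Xr = np.hstack([X0r, (U.T @ x)[:, None]])
            yrj = yr
        Wv = Xr / vr[:, None]
        xtx = Xr.T @ Wv
        xty = Wv.T @ yrj
        beta = np.linalg.solve(xtx, xty)
        resid = yrj - Xr @ beta
        dof = n - Xr.shape[1]
        sigma2 = float(resid @ (resid / vr)) / dof
        cov = sigma2 * np.linalg.inv(xtx)
        alpha = float(beta[-1])
        se = float(np.sqrt(cov[-1, -1]))
        t = alpha / se
        p = float(2 * stats.t.sf(abs(t), dof))
        results.append(AssociationResult(ids[j], alpha, se, max(p, np.finfo(float).tiny)))
    return results


def group_phenotype_test(
    values: pd.Series | np.ndarray,
    grouping: Sequence,
) -> dict:
    """Two-sample comparison with F-test-guided choice of t test.

    ``grouping`` assigns each value to one of exactly two groups.  An F test
    of variance equality at 0.05 selects the pooled t test (variances
    compatible) or Welch's unequal-variance t test.  Returns the t statistic,
    two-sided p value, group means and a significance star ('' / '*' / '**'
    at 0.05 / 0.01).  The result is invariant to swapping group labels.
    """
    values = np.asarray(values, dtype=float)
    groups = pd.unique(pd.Series(grouping))
    if len(groups) != 2:
        raise ValueError("grouping must define exactly two groups")
    g = np.asarray(grouping)
    a = values[g == groups[0]]
    b = values[g == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        equal_var = True
        p_f = 1.0
    else:
        hi, lo = max(va, vb), min(va, vb)
        dfn = (len(a) - 1) if va >= vb else (len(b) - 1)
        dfd = (len(b) - 1) if va >= vb else (len(a) - 1)
        f = hi / lo if lo > 0 else np.inf
        p_f = 2 * min(stats.f.sf(f, dfn, dfd), 1 - stats.f.sf(f, dfn, dfd))
        equal_var = p_f >= 0.05
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(t), float(p)
    if np.isnan(p):  # both groups constant and equal
        t, p = 0.0, 1.0
    star = "**" if p < 0.01 else ("*" if p < 0.05 else "")
    return {
        "t": t,
        "p": p,
        "equal_var": equal_var,
        "f_test_p": float(p_f),
        "means": {str(groups[0]): float(a.mean()), str(groups[1]): float(b.mean())},
        "stars": star,
    }


def derive_yield_traits(
    lint_weight: float, seed_cotton_weight: float, seeds_per_sample: float = 100.0
) -> dict[str, float]:
    """Lint percentage, lint index and seed index from sample weights.

    lint% = 100 * lint weight / seed-cotton weight; the lint index is the
    lint obtained per 100 seeds and the seed index the weight of 100 seeds,
    both derived from the same sample scaled to ``seeds_per_sample`` seeds.
    """
    if seed_cotton_weight <= 0 or lint_weight < 0:
        raise ValueError("weights must be positive (lint may be zero)")
    if lint_weight > seed_cotton_weight:
        raise ValueError("lint cannot outweigh the seed cotton it came from")
    seed_weight = seed_cotton_weight - lint_weight
    scale = 100.0 / seeds_per_sample
    return {
        "lint_percentage": 100.0 * lint_weight / seed_cotton_weight,
        "lint_index": lint_weight * scale,
        "seed_index": seed_weight * scale,
    }


def phenotype_means(table: pd.DataFrame, trait: str) -> pd.Series:
    """Mean value per accession for one trait across environments."""
    sub = table[table["trait"] == trait]
    return sub.groupby("accession")["value"].mean()
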