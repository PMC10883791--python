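"""PCA-based outlier detection for loci associated with population structure
or life-history tactics, Storey q-values, and the F_ST contrast between
tactic groups restricted to the flagged loci.

The scan regresses each locus's (imputed, standardized) dosage vector on the
first K principal-component score vectors; the vector of K regression
z-scores per locus is summarized by its Mahalanobis distance, rescaled by a
genomic inflation factor, and referred to a chi-squared distribution with K
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .structure import multilocus_theta, pca_genotypes, weir_cockerham_components

__all__ = ["OutlierScan", "scree_select_k", "pcadapt_scan", "estimate_pi0",
           "qvalue_storey", "tactic_fst_contrast"]


@dataclass
class OutlierScan:
    k: int
    table: pd.DataFrame        # chrom, pos, d2, p, q, outlier (NaN rows = loci excluded)
    z: np.ndarray              # (n_loci_used, K)
    gif: float
    q_threshold: float

    @property
    def outlier_loci(self) -> pd.DataFrame:
        return self.table[self.table["outlier"].fillna(False)]


def scree_select_k(gm: GenotypeMatrix, k_max: int = 20) -> tuple[int, pd.DataFrame]:
    """Automated scree elbow: the K before the largest second difference of
    the sorted eigenvalues.  Returns (K, scree table) so the choice can be
    overridden by eye, as is usual with scree plots."""
    k_max = int(min(k_max, gm.n_samples - 1))
    if k_max < 1:
        raise ValueError("k_max clipped below 1: need more samples")
    pca = pca_genotypes(gm, n_axes=k_max)
    eig = pca["eigenvalues"][:k_max]
    scree = pd.DataFrame({"axis": np.arange(1, len(eig) + 1),
                          "eigenvalue": eig,
                          "explained": pca["explained"][:len(eig)]})
    if len(eig) < 3:
        return max(1, len(eig) - 1), scree
    second_diff = eig[:-2] - 2 * eig[1:-1] + eig[2:]
    k = int(np.argmax(second_diff) + 1)
    return max(k, 1), scree


def estimate_pi0(p_values: np.ndarray, lambdas: np.ndarray | None = None
                 ) -> float:
    """Null-proportion estimate: ``#{p > lambda} / (m (1 - lambda))`` on a
    lambda grid, extrapolated to lambda = 1 with a cubic fit, clipped to
    (1/m, 1]."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    lambdas = (np.arange(0.05, 0.901, 0.05) if lambdas is None
               else np.asarray(lambdas))
    pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lambdas])
    if np.allclose(pi0_lam, pi0_lam[0]):
        pi0 = float(pi0_lam[0])
    else:
        coef = np.polyfit(lambdas, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, 1.0))
    return min(max(pi0, 1.0 / m), 1.0)


def qvalue_storey(p_values: np.ndarray, lambdas: np.ndarray | None = None
                  ) -> np.ndarray:
    """Storey q-values with smoother-extrapolated pi0.

    pi0 is estimated on the grid lambda = 0.05, 0.10, ..., 0.90 as
    ``#{p > lambda} / (m (1 - lambda))``, a cubic polynomial is fit to the
    grid and evaluated at lambda = 1, and the result is clipped to (0, 1].
    q_i = min over t >= p_i of ``pi0 * m * t / #{p <= t}`` evaluated at the
    observed p-values (the usual step-down form).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    pi0 = estimate_pi0(p, lambdas)

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def pcadapt_scan(gm: GenotypeMatrix, k: int, q_threshold: float = 0.01
                 ) -> OutlierScan:
    """Outlier scan: per-locus regression z-scores on K PCs -> Mahalanobis
    distance -> GIF-rescaled chi-squared p-values -> Storey q-values.

    Constant or all-missing loci are excluded from the statistics and carry
    NaN rows in the output table; flagged loci satisfy q < q_threshold.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if k >= gm.n_samples - 1:
        raise ValueError("K must be smaller than n_samples - 1")
    from .structure import _impute_standardize

    x, keep = _impute_standardize(gm.dosage)
    n = x.shape[0]
    pca = pca_genotypes(gm, n_axes=k)
    scores = pca["scores"]
    # orthonormal basis of the score space
    qmat, _ = np.linalg.qr(scores)
    beta = qmat.T @ x                            # (K, L) coefficients in the Q basis
    rss = (x ** 2).sum(axis=0) - (beta ** 2).sum(axis=0)
    dof = max(n - k, 1)
    sigma = np.sqrt(np.maximum(rss, 0.0) / dof)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma > 0, beta / sigma, 0.0).T   # (L, K)

    cov = np.cov(z, rowvar=False)
    cov = np.atleast_2d(cov)
    inv = np.linalg.pinv(cov)
    centered = z - z.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centered, inv, centered)
    gif = float(np.median(d2) / stats.chi2.median(k))
    if gif <= 0:
        gif = 1.0
    p = stats.chi2.sf(d2 / gif, df=k)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = qvalue_storey(p)

    table = pd.DataFrame({"chrom": gm.loci["chrom"], "pos": gm.loci["pos"],
                          "d2": np.nan, "p": np.nan, "q": np.nan,
                          "outlier": pd.array([None] * gm.n_loci, dtype="boolean")})
    idx = np.flatnonzero(keep)
    table.loc[idx, "d2"] = d2
    table.loc[idx, "p"] = p
    table.loc[idx, "q"] = q
    table.loc[idx, "outlier"] = q < q_threshold
    return OutlierScan(k=k, table=table, z=z, gif=gif, q_threshold=q_threshold)


def tactic_fst_contrast(gm: GenotypeMatrix, outlier_mask: np.ndarray,
                        tactic_column: str = "tactic"
                        ) -> tuple[float, float, float]:
    """Multilocus WC-84 theta between tactic groups using all loci versus
    only the flagged loci; returns (theta_all, theta_outliers, ratio)."""
    outlier_mask = np.asarray(outlier_mask)
    if outlier_mask.dtype != bool:
        raise ValueError("outlier_mask must be boolean")
    if not outlier_mask.any():
        raise ValueError("empty outlier set")
    labels = gm.samples[tactic_column].to_numpy()
    ok = pd.notna(labels)
    sub = gm.take(sample_idx=ok)
    labels = labels[ok]
    comp_all = weir_cockerham_components(sub, labels)
    theta_all = multilocus_theta(comp_all)
    comp_out = comp_all[outlier_mask].copy()
    theta_out = multilocus_theta(comp_out)
    ratio = theta_out / theta_all if theta_all and theta_all != 0 else np.nan
    return theta_all, theta_out, ratio
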