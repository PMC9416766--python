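"""Mixed-model association on sire evaluations (EMMAX-style two-stage scan).

The response is a per-individual trait value (typically the bull EBV, taken
at reliability > 0.5); relatedness is controlled with an identity-by-state
(IBS) kinship matrix estimated from the markers.  A single-component REML of
y = mu + g + e with cov(g) = sigma_g^2 K ("pseudo-heritability") fixes the
variance components, after which each SNP is tested by generalized least
squares in the rotated (eigen) space of K.  Missing dosages are mean-imputed
per SNP after call-rate QC; p-values use the t distribution with n - 2
degrees of freedom; multiple testing is controlled by Bonferroni.

The cross-trait comparison regresses the allele-substitution effects of one
scan on another over SNPs above a minor-allele-frequency floor (optionally
the top-k by significance), reporting R^2 and slope — the marker-level
analogue of a genetic correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .plink import GenotypeMatrix

__all__ = [
    "qc_filter",
    "ibs_kinship",
    "null_reml",
    "NullModel",
    "scan",
    "bonferroni",
    "cross_trait_effects",
]


def qc_filter(geno: GenotypeMatrix, min_call_rate: float = 0.90) -> GenotypeMatrix:
    """Retain SNPs genotyped in more than ``min_call_rate`` of individuals."""
    keep = geno.call_rate() > min_call_rate
    if not keep.any():
        raise ValueError("no SNPs pass the call-rate filter")
    return geno.subset_snps(keep)


def ibs_kinship(geno: GenotypeMatrix) -> np.ndarray:
    """Identity-by-state similarity: K_ij = mean over SNPs of 1 - |d_i - d_j| / 2.

    Missing calls are excluded pairwise; a pair with no overlapping SNPs is
    an error.  The diagonal is 1 for complete data.
    """
    D = geno.dosage
    miss = np.isnan(D)
    Df = np.nan_to_num(D)
    n = D.shape[0]
    obs = (~miss).astype(float)
    overlap = obs @ obs.T
    if np.any(overlap == 0):
        raise ValueError("individual pair with no overlapping genotyped SNPs")
    # sum over SNPs of |d_i - d_j| restricted to jointly observed SNPs:
    # |a-b| = a + b - 2 min(a,b); with dosages in {0,1,2} use indicator trick
    # simpler: accumulate per dosage level
    total = np.zeros((n, n))
    for a in (0.0, 1.0, 2.0):
        Ia = ((Df == a) & ~miss).astype(float)
        for b in (0.0, 1.0, 2.0):
            if abs(a - b) == 0:
                continue
            Ib = ((Df == b) & ~miss).astype(float)
            total += abs(a - b) * (Ia @ Ib.T)
    K = 1.0 - total / (2.0 * overlap)
    return 0.5 * (K + K.T)


@dataclass
class NullModel:
    h2: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    eigvals: np.ndarray
    eigvecs: np.ndarray


def null_reml(
    y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None, eig=None
) -> NullModel:
    """Single-component genomic REML: y = Xb + g + e, cov(g) = sigma_g^2 K.

    Maximizes the restricted likelihood over delta = sigma_e^2 / sigma_g^2 on
    the eigenspectrum of K (grid search plus bounded refinement).  The
    returned ``h2`` is the pseudo-heritability sigma_g^2 / (sigma_g^2 +
    sigma_e^2).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    p = X.shape[1]
    if eig is None:
        lam, U = np.linalg.eigh(np.asarray(K, dtype=float))
    else:
        lam, U = eig
    if lam.min() < -1e-6 * max(1.0, np.trace(K) / n):
        raise ValueError("kinship matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X

    def neg2_restricted(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = lam + delta
        XtWX = Xs.T @ (Xs / w[:, None])
        XtWy = Xs.T @ (ys / w)
        beta = np.linalg.solve(XtWX, XtWy)
        r = ys - Xs @ beta
        rss = float(np.sum(r * r / w))
        sign, logdet_x = np.linalg.slogdet(XtWX)
        return (n - p) * np.log(rss) + np.sum(np.log(w)) + logdet_x

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg2_restricted(g) for g in grid]
    i0 = int(np.argmin(vals))
    lo = grid[max(0, i0 - 1)]
    hi = grid[min(len(grid) - 1, i0 + 1)]
    res = minimize_scalar(neg2_restricted, bounds=(lo, hi), method="bounded")
    delta = float(np.exp(res.x))
    w = lam + delta
    XtWX = Xs.T @ (Xs / w[:, None])
    beta = np.linalg.solve(XtWX, Xs.T @ (ys / w))
    r = ys - Xs @ beta
    sigma_g2 = float(np.sum(r * r / w) / (n - p))
    sigma_e2 = sigma_g2 * delta
    return NullModel(
        h2=1.0 / (1.0 + delta),
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        loglik=-0.5 * float(res.fun),
        eigvals=lam,
        eigvecs=U,
    )


def scan(
    y: np.ndarray,
    geno: GenotypeMatrix,
    K: np.ndarray | None = None,
    null: NullModel | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP GLS association with variance components fixed at the null fit.

    Monomorphic SNPs get NaN effect/p and are flagged ``excluded``; missing
    dosages are mean-imputed per SNP.  With K = I the scan reduces exactly
    to per-SNP ordinary least squares.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    X0 = np.ones((n, 1))
    if covariates is not None:
        X0 = np.column_stack([X0, covariates])
    if null is None:
        if K is None:
            raise ValueError("supply a kinship matrix or a fitted null model")
        null = null_reml(y, K, X0)
    lam, U = null.eigvals, null.eigvecs
    w = 1.0 / (lam + null.sigma_e2 / null.sigma_g2)
    ys = U.T @ y
    X0s = U.T @ X0

    D = geno.dosage.copy()
    maf = geno.maf()
    call = geno.call_rate()
    mono = np.logical_or(maf == 0, np.isnan(maf))
    mean = np.nanmean(np.where(np.isnan(D), np.nan, D), axis=0)
    idx = np.where(np.isnan(D))
    D[idx] = np.take(mean, idx[1])
    Ds = U.T @ D

    p_cov = X0s.shape[1]
    q = p_cov + 1
    effects = np.full(geno.n_snps, np.nan)
    ses = np.full(geno.n_snps, np.nan)
    pvals = np.full(geno.n_snps, np.nan)
    # per-SNP weighted regression of ys on [X0s, snp]
    wX0 = X0s * w[:, None]
    A00 = X0s.T @ wX0  # (p, p), shared
    b0 = wX0.T @ ys
    for j in range(geno.n_snps):
        if mono[j]:
            continue
        x = Ds[:, j]
        wx = w * x
        A = np.empty((q, q))
        A[:p_cov, :p_cov] = A00
        A[:p_cov, -1] = X0s.T @ wx
        A[-1, :p_cov] = A[:p_cov, -1]
        A[-1, -1] = x @ wx
        b = np.concatenate([b0, [x @ (w * ys)]])
        try:
            coef = np.linalg.solve(A, b)
            Ainv_last = np.linalg.inv(A)[-1, -1]
        except np.linalg.LinAlgError:
            continue
        resid = ys - np.column_stack([X0s, x]) @ coef
        dof = n - 2
        s2 = float(np.sum(w * resid * resid) / dof) * null.sigma_g2
        se = np.sqrt(Ainv_last * s2 / null.sigma_g2)
        effects[j] = coef[-1]
        ses[j] = se
        tstat = coef[-1] / se if se > 0 else np.nan
        pvals[j] = 2.0 * stats.t.sf(abs(tstat), dof)
    return pd.DataFrame(
        {
            "snp": geno.snp_ids,
            "chrom": geno.chrom,
            "pos": geno.pos,
            "effect": effects,
            "se": ses,
            "p": pvals,
            "maf": maf,
            "call_rate": call,
            "excluded": mono,
        }
    )


def bonferroni(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """SNPs significant after Bonferroni correction over the tested count."""
    tested = results[~results["p"].isna()]
    m = len(tested)
    if m == 0:
        return tested
    return tested[tested["p"] <= alpha / m]


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    return alpha / m


def cross_trait_effects(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    maf_min: float = 0.10,
    top_k: int | None = None,
):
    """Compare allele-substitution effects across two scans.

    Restricts to SNPs with MAF above ``maf_min`` present (and tested) in both
    scans, optionally the ``top_k`` most significant in scan a; returns
    (R^2, slope, paired table) from the regression of effect_a on effect_b.
    """
    a = results_a[(results_a["maf"] > maf_min) & ~results_a["p"].isna()]
    b = results_b[(results_b["maf"] > maf_min) & ~results_b["p"].isna()]
    merged = a.merge(b, on="snp", suffixes=("_a", "_b"))
    if top_k is not None:
        merged = merged.nsmallest(top_k, "p_a")
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared SNPs after filtering")
    reg = stats.linregress(merged["effect_b"], merged["effect_a"])
    return reg.rvalue**2, reg.slope, merged[["snp", "effect_a", "effect_b", "p_a", "p_b", "maf_a"]]
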