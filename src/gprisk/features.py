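"""Within-fold SNP ranking: mixed-model GWAS p-values or case/control
allele-frequency differences.

Both rankers are filters — they order SNPs for top-k selection inside a
training fold; no significance claims are made.  The GWAS route treats the
0/1 phenotype as quantitative, estimates the polygenic variance ratio once
per fold by REML on the eigendecomposed genomic relationship matrix, then
scores every SNP with a Wald t-test in the rotated (whitened) regression —
the single-variance-component shortcut that makes per-SNP mixed models
affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io_plink import GenotypeMatrix, mean_impute


@dataclass
class RankedFeatures:
    snp_ids: np.ndarray   # best first
    scores: np.ndarray    # p-values (ascending) or |freq difference| (descending)
    method: str           # "gwas_p" or "mean_diff"
    fold_id: int | None = None

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(self.scores):
            raise ValueError("snp_ids and scores length mismatch")


def grm(geno: GenotypeMatrix, imputed: np.ndarray | None = None) -> np.ndarray:
    """VanRaden genomic relationship matrix K = WW' / sum(2 p_j (1-p_j))
    with W the column-centered dosage matrix."""
    if geno.n_samples < 2:
        raise ValueError("GRM requires at least two samples")
    X = imputed if imputed is not None else mean_impute(geno.dosages)[0]
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; GRM undefined")
    W = X[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    return W @ W.T / denom


def _reml_delta(eigvals: np.ndarray, Uy: np.ndarray, UX: np.ndarray) -> float:
    """REML estimate of delta = sigma2_e / sigma2_g on the rotated model.

    Profiles the residual quadratic form over the eigenvalue spectrum of K
    and optimizes the restricted likelihood over log10(delta).
    """
    n, q = UX.shape

    def neg_restricted_ll(log_delta: float) -> float:
        d = eigvals + 10.0 ** log_delta
        Xd = UX / d[:, None]
        XtVX = UX.T @ Xd
        beta = np.linalg.solve(XtVX, Xd.T @ Uy)
        r = Uy - UX @ beta
        rss = float(np.sum(r * r / d))
        ll = -0.5 * ((n - q) * np.log(rss / (n - q)) + np.sum(np.log(d))
                     + np.linalg.slogdet(XtVX)[1])
        return -ll

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-5.0, 5.0),
                                   method="bounded",
                                   options={"xatol": 1e-4})
    return float(10.0 ** res.x)


def lmm_gwas(geno: GenotypeMatrix, y: np.ndarray, covariates: np.ndarray | None,
             K: np.ndarray, imputed: np.ndarray | None = None,
             fold_id: int | None = None) -> RankedFeatures:
    """Per-SNP association p-values from a single-variance-component LMM.

    The variance ratio is estimated once under the null model (intercept +
    covariates + polygenic effect with covariance K); each SNP is then
    tested by a Wald t-test in the whitened regression.  With K = I this
    reduces exactly to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = imputed if imputed is not None else mean_impute(geno.dosages)[0]
    C = np.ones((n, 1))
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        keep = []
        basis = C
        for j in range(cov.shape[1]):
            trial = np.column_stack([basis, cov[:, j]])
            if np.linalg.matrix_rank(trial) > basis.shape[1]:
                basis = trial
                keep.append(j)
            else:
                warnings.warn(f"dropping collinear covariate column {j}")
        C = basis

    K = 0.5 * (K + K.T)
    eigvals, U = np.linalg.eigh(K)
    if eigvals.min() < -1e-6 * max(1.0, abs(eigvals.max())):
        raise ValueError("kinship matrix is not positive semi-definite")
    eigvals = np.clip(eigvals, 0.0, None)

    Uy = U.T @ y
    UC = U.T @ C
    delta = _reml_delta(eigvals, Uy, UC)
    w = 1.0 / np.sqrt(eigvals + delta)  # whitening weights

    yw = Uy * w
    Cw = UC * w[:, None]
    UM = (U.T @ X) * w[:, None]

    # residualize phenotype and markers on the whitened covariates
    Q, _ = np.linalg.qr(Cw)
    y_res = yw - Q @ (Q.T @ yw)
    M_res = UM - Q @ (Q.T @ UM)

    ss = np.sum(M_res * M_res, axis=0)
    dof = n - C.shape[1] - 1
    pvals = np.ones(geno.n_snps)
    ok = ss > 1e-12
    beta = np.zeros(geno.n_snps)
    beta[ok] = (M_res[:, ok].T @ y_res) / ss[ok]
    rss = np.sum(y_res * y_res) - beta**2 * ss
    rss = np.clip(rss, 1e-300, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / ss)
        tstat = np.where(ok, beta / se, 0.0)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    order = np.lexsort((geno.snp_ids, pvals))  # ascending p, ties by snp_id
    return RankedFeatures(snp_ids=geno.snp_ids[order], scores=pvals[order],
                          method="gwas_p", fold_id=fold_id)


def mean_diff_rank(geno: GenotypeMatrix, y: np.ndarray,
                   fold_id: int | None = None) -> RankedFeatures:
    """Rank SNPs by |allele frequency in cases - allele frequency in controls|."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("mean_diff_rank requires both cases and controls")
    dos = geno.dosages.astype(float)
    dos[geno.dosages < 0] = np.nan

    def freq(mask: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(dos[mask], axis=0) / 2.0

    diff = np.abs(freq(y == 1) - freq(y == 0))
    diff = np.where(np.isnan(diff), 0.0, diff)
    order = np.lexsort((geno.snp_ids, -diff))  # descending |diff|, ties by snp_id
    return RankedFeatures(snp_ids=geno.snp_ids[order], scores=diff[order],
                          method="mean_diff", fold_id=fold_id)


# SNP-count grid explored when tuning the inclusion threshold
K_GRID = (5, 10, 25, 100, 750, 4000, 7500, 10000, 12500, 15000)


def select_top_k(ranked: RankedFeatures, k: int) -> np.ndarray:
    """First min(k, available) snp_ids of the ranking, order preserved."""
    if k is None or k < 1:
        raise ValueError("k must be a positive integer")
    return ranked.snp_ids[: min(k, len(ranked.snp_ids))]
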