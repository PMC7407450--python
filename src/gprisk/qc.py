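"""Marker quality control and windowed LD pruning.

Filters are applied in the fixed order call rate -> MAF -> exact
Hardy-Weinberg test, each SNP landing in exactly one removal category.
Thresholds follow common GWAS practice for array data: SNPs are *excluded*
when the genotyping rate is <= 0.95, when MAF <= 0.05 (inclusive), or when
the two-sided HWE exact p-value is < 1e-7.  LD pruning is the
``--indep-pairwise 50 5 0.7`` idiom: a 50-SNP window advanced 5 SNPs at a
time within each chromosome, greedily removing one SNP of the most
correlated pair (squared Pearson correlation of mean-imputed dosages) until
no pair above the threshold remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_plink import MISSING, GenotypeMatrix, mean_impute


@dataclass
class QCConfig:
    maf_exclude_max: float = 0.05   # inclusive: MAF <= this is removed
    callrate_min: float = 0.95      # exclusive: call rate <= this is removed
    hwe_p_min: float = 1e-7         # removed when p < this
    ld_r2_max: float = 0.7
    ld_window: int = 50
    ld_step: int = 5

    def validate(self) -> None:
        if not 0 <= self.maf_exclude_max <= 0.5:
            raise ValueError("maf_exclude_max must be in [0, 0.5]")
        if not 0 <= self.callrate_min <= 1:
            raise ValueError("callrate_min must be in [0, 1]")
        if not 0 < self.hwe_p_min <= 1:
            raise ValueError("hwe_p_min must be in (0, 1]")
        if not 0 < self.ld_r2_max <= 1:
            raise ValueError("ld_r2_max must be in (0, 1]")
        if self.ld_window < 2 or self.ld_step < 1:
            raise ValueError("ld_window must be >= 2 and ld_step >= 1")


@dataclass
class QCReport:
    n_input: int
    removed_callrate: list = field(default_factory=list)
    removed_maf: list = field(default_factory=list)
    removed_hwe: list = field(default_factory=list)
    kept: list = field(default_factory=list)

    @property
    def n_remaining(self) -> int:
        return len(self.kept)

    def counts(self) -> dict:
        return {
            "input": self.n_input,
            "callrate": len(self.removed_callrate),
            "maf": len(self.removed_maf),
            "hwe": len(self.removed_hwe),
            "remaining": self.n_remaining,
        }


def snp_callrate(geno: GenotypeMatrix) -> np.ndarray:
    return 1.0 - (geno.dosages == MISSING).mean(axis=0)


def snp_maf(geno: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing calls.

    All-missing SNPs get NaN.  Dosages coded toward the major allele are
    folded, so the result is always in [0, 0.5].
    """
    dos = geno.dosages.astype(float)
    dos[geno.dosages == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(dos, axis=0) / 2.0
    return np.where(freq > 0.5, 1.0 - freq, freq)


def genotype_counts(geno: GenotypeMatrix) -> np.ndarray:
    """p x 3 array of (hom-major, het, hom-minor) counts over non-missing calls."""
    out = np.empty((geno.n_snps, 3), dtype=int)
    for g in (0, 1, 2):
        out[:, g] = (geno.dosages == g).sum(axis=0)
    return out[:, [0, 1, 2]]


def hwe_het_distribution(n_total: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele totals.

    Returns (het_values, probabilities) for ``n_total`` genotyped samples
    carrying ``n_rare`` copies of the rarer allele.  Built from the standard
    probability recurrence over heterozygote counts, so only ratios — never
    factorials — are formed.
    """
    if n_total < 1:
        raise ValueError("at least one genotype required")
    if not 0 <= n_rare <= n_total:
        raise ValueError("rare-allele count must be in [0, n_total]")
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.empty(len(het_values))
    # unnormalized recurrence: P(h+2)/P(h) = 4*hr*hc / ((h+2)*(h+1))
    # where hr, hc are the rare/common homozygote counts at h hets
    probs[0] = 1.0
    for k in range(1, len(het_values)):
        h = het_values[k - 1]
        hr = (n_rare - h) // 2
        hc = n_total - h - hr
        probs[k] = probs[k - 1] * 4.0 * hr * hc / ((h + 2.0) * (h + 1.0))
        if probs[k] > 1e250:  # rescale to avoid overflow; ratios are preserved
            probs /= probs[k]
    probs /= probs.sum()
    return het_values, probs


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value (no mid-p correction).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    het_values, probs = hwe_het_distribution(n, n_rare)
    obs = probs[het_values == n_het]
    if len(obs) != 1:
        raise ValueError(
            f"heterozygote count {n_het} inconsistent with allele totals "
            f"(expected parity {n_rare % 2})"
        )
    p = probs[probs <= obs[0] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    counts = genotype_counts(geno)
    return np.array([hwe_exact_p(a, b, c) if a + b + c > 0 else np.nan
                     for a, b, c in counts])


def apply_qc(geno: GenotypeMatrix, snps: pd.DataFrame, cfg: QCConfig | None = None
             ) -> tuple[GenotypeMatrix, pd.DataFrame, QCReport]:
    """Apply the call-rate, MAF and HWE filters in order; returns the filtered
    cohort and a report assigning each removed SNP to exactly one category."""
    cfg = cfg or QCConfig()
    cfg.validate()
    report = QCReport(n_input=geno.n_snps)

    callrate = snp_callrate(geno)
    maf = snp_maf(geno)
    hwe = hwe_pvalues(geno)

    fail_cr = callrate <= cfg.callrate_min
    fail_maf = ~fail_cr & (np.isnan(maf) | (maf <= cfg.maf_exclude_max))
    fail_hwe = ~fail_cr & ~fail_maf & (hwe < cfg.hwe_p_min)
    keep = ~(fail_cr | fail_maf | fail_hwe)

    ids = geno.snp_ids
    report.removed_callrate = list(ids[fail_cr])
    report.removed_maf = list(ids[fail_maf])
    report.removed_hwe = list(ids[fail_hwe])
    report.kept = list(ids[keep])
    if not keep.any():
        warnings.warn("QC removed every SNP; returning an empty cohort")
    idx = np.where(keep)[0]
    return geno.subset_snps(idx), snps.iloc[idx].reset_index(drop=True), report


def ld_prune(geno: GenotypeMatrix, snps: pd.DataFrame, cfg: QCConfig | None = None
             ) -> list:
    """Windowed greedy LD pruning; returns kept snp_ids in genomic order.

    Requires the SNP table sorted by (chromosome, position).  Within each
    window the most correlated pair above the r-squared threshold loses its
    lower-MAF member (ties drop the later position); windows slide over the
    currently kept SNPs and sweeps repeat until a full pass removes nothing.
    """
    cfg = cfg or QCConfig()
    cfg.validate()
    for chrom, grp in snps.groupby("chromosome", sort=False):
        if not grp["position"].is_monotonic_increasing:
            raise ValueError(f"SNPs on chromosome {chrom} are not position-sorted")

    X, _ = mean_impute(geno.dosages)
    maf = snp_maf(geno)
    pos = snps["position"].to_numpy()
    kept_ids: list = []

    for chrom in pd.unique(snps["chromosome"]):
        cols = np.where((snps["chromosome"] == chrom).to_numpy())[0]
        alive = list(cols)
        changed = True
        while changed:
            changed = False
            start = 0
            while start < len(alive):
                window = alive[start:start + cfg.ld_window]
                if len(window) > 1:
                    removed = _prune_window(X, maf, pos, window, cfg.ld_r2_max)
                    if removed:
                        alive = [j for j in alive if j not in removed]
                        changed = True
                start += cfg.ld_step
        kept_ids.extend(geno.snp_ids[j] for j in alive)
    return kept_ids


def _prune_window(X: np.ndarray, maf: np.ndarray, pos: np.ndarray,
                  window: list, r2_max: float) -> set:
    """Greedy removal inside one window; returns the set of removed columns."""
    idx = list(window)
    removed: set = set()
    sub = X[:, idx]
    sd = sub.std(axis=0)
    ok = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sub, rowvar=False)
    r2 = np.square(r)
    r2[~ok, :] = 0.0
    r2[:, ~ok] = 0.0
    np.fill_diagonal(r2, 0.0)
    while True:
        flat = np.argmax(r2)
        a, b = np.unravel_index(flat, r2.shape)
        if r2[a, b] <= r2_max:
            break
        ja, jb = idx[a], idx[b]
        if maf[ja] < maf[jb]:
            drop = a
        elif maf[jb] < maf[ja]:
            drop = b
        else:  # tie on MAF: drop the later genomic position
            drop = a if pos[ja] > pos[jb] else b
        removed.add(idx[drop])
        r2[drop, :] = 0.0
        r2[:, drop] = 0.0
    return removed
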