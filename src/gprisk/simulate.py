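"""Synthetic SNP cohorts under a liability-threshold disease model.

The generator emulates the statistical structure of a purebred-dog
case/control genotyping study: blocky linkage disequilibrium (haplotype
blocks of tightly correlated SNPs, near-independence between blocks), a
polygenic liability with a specified heritability, a low population
prevalence, and three clinical covariates (sex, neuter status, body weight)
with liability-scale effects.

Defaults mirror the Labrador Retriever cruciate-ligament-rupture setting:
622 individuals, prevalence 0.0579, liability heritability 0.4 (the middle
of published 0.3-0.5 estimates), ~20 kb haplotype blocks.

Haplotypes are drawn per block from a pool of 20 founder haplotypes whose
alleles follow a thresholded AR(1) Gaussian process, giving a tunable
within-block correlation; individual haplotypes copy a random founder with a
small per-site mutation probability.  Liability is the sum of a scaled
genetic score, the covariate effects and an independent Gaussian residual;
cases are the individuals above the realized (1-K) liability quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm

from .io_plink import MISSING, GenotypeMatrix, write_plink
from . import evaluate


@dataclass
class SimConfig:
    """Study-design parameters of a simulated cohort."""

    n_individuals: int = 622
    n_snps: int = 100_000
    block_size: int = 10              # SNPs per haplotype block
    within_block_r: float = 0.6       # target adjacent-SNP genotype correlation
    n_causal: int = 1000
    h2_liability: float = 0.4
    prevalence_K: float = 0.0579
    # liability-scale effects: (per kg of body weight, male vs female, neutered vs intact)
    covariate_effects: tuple = (0.04, 0.2, 0.4)
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.01
    n_chromosomes: int = 38
    n_founders: int = 20
    mutation_rate: float = 0.02
    block_span_bp: int = 20_000       # genomic extent of one block
    weight_mean_female: float = 30.0  # kg
    weight_mean_male: float = 34.0
    weight_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.n_individuals:
            raise ValueError("n_individuals must be positive")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not 0.0 <= self.h2_liability <= 1.0:
            raise ValueError("h2_liability must be in [0,1]")
        if not 0.0 < self.prevalence_K < 1.0:
            raise ValueError("prevalence_K must be in (0,1)")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if not 0.0 < self.within_block_r < 1.0:
            raise ValueError("within_block_r must be in (0,1)")


@dataclass
class SimulatedCohort:
    """A generated cohort plus the generative truth used to validate models."""

    geno: GenotypeMatrix
    snps: pd.DataFrame
    samples: pd.DataFrame
    true_effects: np.ndarray    # per-SNP liability effect, 0 for non-causal
    true_liability: np.ndarray
    genetic_score: np.ndarray
    liability_threshold: float
    config: SimConfig

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy().astype(int)


def _copula_rho(target_r: float, mean_maf: float) -> float:
    """Gaussian-copula correlation giving binary correlation ``target_r``
    between two thresholded sites at allele frequency ``mean_maf``."""
    a = norm.ppf(mean_maf)
    pq = mean_maf * (1.0 - mean_maf)

    def binary_corr(rho: float) -> float:
        p11 = multivariate_normal.cdf([a, a], cov=[[1.0, rho], [rho, 1.0]])
        return (p11 - mean_maf**2) / pq

    lo, hi = 0.0, 0.9999
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if binary_corr(mid) < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a reproducible cohort under ``cfg`` (identical seeds give
    identical cohorts)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_individuals, cfg.n_snps

    n_blocks = int(np.ceil(p / cfg.block_size))
    # mutation dilutes haplotype correlation by (1-mu)^2; compensate the copula target
    target = min(0.99, cfg.within_block_r / (1.0 - cfg.mutation_rate) ** 2)
    rho_z = _copula_rho(target, float(np.mean(cfg.maf_range)))

    dosages = np.empty((n, p), dtype=np.int8)
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=p)
    ar_noise = np.sqrt(1.0 - rho_z**2)
    for b in range(n_blocks):
        lo, hi = b * cfg.block_size, min((b + 1) * cfg.block_size, p)
        bs = hi - lo
        # founder pool: AR(1) Gaussian thresholded at the per-site frequency
        z = np.empty((cfg.n_founders, bs))
        z[:, 0] = rng.standard_normal(cfg.n_founders)
        for j in range(1, bs):
            z[:, j] = rho_z * z[:, j - 1] + ar_noise * rng.standard_normal(cfg.n_founders)
        pool = (z < norm.ppf(freqs[lo:hi])[None, :]).astype(np.int8)
        # two haplotypes per individual, copied from random founders
        idx = rng.integers(0, cfg.n_founders, size=2 * n)
        haps = pool[idx]
        mut = rng.random(haps.shape) < cfg.mutation_rate
        if mut.any():
            haps = np.where(mut, (rng.random(haps.shape) < freqs[lo:hi][None, :]), haps)
        dosages[:, lo:hi] = (haps[:n] + haps[n:]).astype(np.int8)

    # decide missingness now so minor-allele orientation can follow the
    # *observed* frequency, the same rule the PLINK reader applies — this is
    # what keeps write/read round-trips bit-exact
    miss = (rng.random(dosages.shape) < cfg.missing_rate) if cfg.missing_rate > 0 \
        else None
    if miss is not None:
        obs = np.where(miss, np.nan, dosages.astype(float))
        with np.errstate(invalid="ignore"):
            realized = np.nanmean(obs, axis=0) / 2.0
        realized = np.where(np.isnan(realized), 0.0, realized)
    else:
        realized = dosages.mean(axis=0) / 2.0
    flip = realized > 0.5  # ties at 0.5 keep the generated orientation
    dosages[:, flip] = 2 - dosages[:, flip]

    # polygenic liability
    true_effects = np.zeros(p)
    genetic_score = np.zeros(n)
    if cfg.h2_liability > 0 and cfg.n_causal > 0:
        causal = rng.choice(p, size=cfg.n_causal, replace=False)
        alpha = rng.standard_normal(cfg.n_causal)
        g_raw = dosages[:, causal].astype(float) @ alpha
        sd = g_raw.std()
        if sd == 0:
            raise ValueError("degenerate genotypes: genetic score has zero variance")
        scale = np.sqrt(cfg.h2_liability) / sd
        true_effects[causal] = alpha * scale
        genetic_score = g_raw * scale

    # covariates
    b_w, b_sex, b_neut = cfg.covariate_effects
    male = rng.random(n) < 0.5
    neutered = rng.random(n) < 0.7
    weight = rng.normal(np.where(male, cfg.weight_mean_male, cfg.weight_mean_female),
                        cfg.weight_sd)
    weight = np.clip(weight, 1.0, None)
    cov_part = b_w * weight + b_sex * male + b_neut * neutered
    var_cov = float(np.var(cov_part))

    resid_var = 1.0 - cfg.h2_liability - var_cov
    if resid_var < 0:
        raise ValueError(
            f"infeasible variance partition: h2={cfg.h2_liability} plus covariate "
            f"variance {var_cov:.3f} exceeds total liability variance 1"
        )
    liability = genetic_score + cov_part + rng.normal(0.0, np.sqrt(resid_var), size=n)

    # threshold at the realized (1-K) quantile so finite-sample prevalence matches K
    t_K = float(np.quantile(liability, 1.0 - cfg.prevalence_K))
    y = (liability > t_K).astype(int)

    if miss is not None:
        dosages[miss] = MISSING

    width = len(str(p))
    snp_ids = np.array([f"snp{j:0{width}d}" for j in range(p)], dtype=object)
    sample_ids = np.array([f"id{i:0{len(str(n))}d}" for i in range(n)], dtype=object)

    n_chrom = max(1, min(cfg.n_chromosomes, n_blocks))
    blocks_per_chrom = int(np.ceil(n_blocks / n_chrom))
    block_of = np.arange(p) // cfg.block_size
    chrom = (block_of // blocks_per_chrom + 1).astype(int)
    within = np.arange(p) % cfg.block_size
    block_on_chrom = block_of % blocks_per_chrom
    spacing = max(1, cfg.block_span_bp // max(1, cfg.block_size))
    position = 1 + block_on_chrom * (2 * cfg.block_span_bp) + within * spacing

    snps = pd.DataFrame({
        "snp_id": snp_ids, "chromosome": chrom.astype(str), "position": position,
        "allele1": "A", "allele2": "C",
        "maf": np.where(flip, 1.0 - realized, realized),
    })
    samples = pd.DataFrame({
        "sample_id": sample_ids, "phenotype": y,
        "sex": np.where(male, "male", "female"),
        "neutered": np.where(neutered, "neutered", "intact"),
        "weight": weight,
    })
    geno = GenotypeMatrix(dosages, sample_ids, snp_ids)
    return SimulatedCohort(geno=geno, snps=snps, samples=samples,
                           true_effects=true_effects, true_liability=liability,
                           genetic_score=genetic_score, liability_threshold=t_K,
                           config=cfg)


def realized_heritability(cohort: SimulatedCohort) -> float:
    """Fraction of realized liability variance carried by the genetic score."""
    var_l = float(np.var(cohort.true_liability))
    if var_l == 0:
        raise ValueError("liability has zero variance")
    return float(np.var(cohort.genetic_score)) / var_l


def oracle_auc(cohort: SimulatedCohort, score) -> float:
    """Mann-Whitney AUC of an arbitrary per-sample score against case status."""
    return evaluate.auc(score, cohort.phenotype)


def save_cohort(cohort: SimulatedCohort, prefix: str | Path) -> None:
    """Write the cohort as PLINK fileset + covariate TSV + generative-truth TSVs."""
    prefix = Path(prefix)
    write_plink(cohort.geno, cohort.snps, cohort.samples, prefix)
    cov = cohort.samples[["sample_id", "sex", "neutered", "weight"]]
    cov.to_csv(prefix.with_suffix(".covar.tsv"), sep="\t", index=False)
    truth_snp = pd.DataFrame({"snp_id": cohort.geno.snp_ids,
                              "true_effect": cohort.true_effects})
    truth_snp.to_csv(prefix.with_suffix(".effects.tsv"), sep="\t", index=False)
    truth_ind = pd.DataFrame({"sample_id": cohort.geno.sample_ids,
                              "true_liability": cohort.true_liability,
                              "genetic_score": cohort.genetic_score})
    truth_ind.to_csv(prefix.with_suffix(".liability.tsv"), sep="\t", index=False)
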