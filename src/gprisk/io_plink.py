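"""Reading and writing PLINK binary filesets (.bed/.bim/.fam) and covariate tables.

The .bed payload is SNP-major: after a three-byte header (``0x6C 0x1B 0x01``)
each SNP occupies ``ceil(n/4)`` bytes, four samples per byte, two bits per
genotype.  On disk the 2-bit codes count copies of allele1 (00 = two copies,
10 = one copy, 11 = zero copies, 01 = missing).  In memory genotypes are
re-oriented so that the dosage counts the *minor* allele, the additive coding
used by every downstream model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing dosage

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit code -> copies of allele1; 3 marks missing
_CODE_TO_A1_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)


class PlinkFormatError(ValueError):
    """Raised when a .bed file has the wrong magic or mode byte."""


class PlinkCorruptError(ValueError):
    """Raised when .bed payload size disagrees with .bim/.fam row counts."""


@dataclass
class GenotypeMatrix:
    """n_samples x n_snps minor-allele dosage matrix.

    Entries are 0, 1, 2 or :data:`MISSING`.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        n, p = self.dosages.shape
        if n != len(self.sample_ids) or p != len(self.snp_ids):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples / {len(self.snp_ids)} SNPs"
            )
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values {bad}; expected 0/1/2/{MISSING}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, index], self.sample_ids, self.snp_ids[index])

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[index, :], self.sample_ids[index], self.snp_ids)


def mean_impute(dosages: np.ndarray, means: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Replace missing dosages with per-SNP means (training-set means if given).

    Returns the imputed float matrix and the per-SNP means used, so the same
    means can be applied to held-out samples.
    """
    X = np.asarray(dosages, dtype=float)
    miss = dosages == MISSING
    if means is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
            means = np.nanmean(np.where(miss, np.nan, X), axis=0)
        means = np.where(np.isnan(means), 0.0, means)
    if miss.any():
        X[miss] = np.broadcast_to(means, X.shape)[miss]
    return X, means


def _validate_snp_table(snps: pd.DataFrame) -> None:
    required = {"snp_id", "chromosome", "position", "allele1", "allele2"}
    missing = required - set(snps.columns)
    if missing:
        raise ValueError(f"SNP table missing columns {sorted(missing)}")
    if snps["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_ids in SNP table")
    if (snps["position"] < 0).any():
        raise ValueError("negative base-pair positions in SNP table")


def _validate_sample_table(samples: pd.DataFrame) -> None:
    required = {"sample_id", "phenotype"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in sample table")


def _orient_to_minor(a1_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each SNP so dosage counts the minor allele.

    Returns (dosages, flipped) where ``flipped[j]`` is True when allele2 is
    the minor allele for SNP j (i.e. on-disk allele1 counts were kept as-is
    only if allele1 is minor; ties at frequency 0.5 resolve to allele1).
    """
    dos = a1_counts.astype(np.int8).copy()
    miss = dos == MISSING
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq1 = np.nanmean(np.where(miss, np.nan, dos.astype(float)), axis=0) / 2.0
    freq1 = np.where(np.isnan(freq1), 0.0, freq1)
    flipped = freq1 > 0.5  # allele1 is the major allele -> count allele2 instead
    if flipped.any():
        cols = np.where(flipped)[0]
        block = dos[:, cols]
        keep_missing = block == MISSING
        block = (2 - block).astype(np.int8)
        block[keep_missing] = MISSING
        dos[:, cols] = block
    return dos, flipped


def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK binary fileset.

    Returns the minor-allele-oriented :class:`GenotypeMatrix`, the SNP table
    (with a computed ``maf`` column) and the sample table with internal 0/1
    phenotype coding.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chromosome", "snp_id", "cm", "position", "allele1", "allele2"],
        dtype={"chromosome": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "sample_id", "pat", "mat", "sex_code", "pheno_code"],
        dtype={"fid": str, "sample_id": str},
    )
    n, p = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed lacks the PLINK magic bytes 0x6C 0x1B")
    if raw[2] != _BED_SNP_MAJOR:
        raise PlinkFormatError(f"{prefix}.bed mode byte {raw[2]:#04x} is not SNP-major 0x01")
    bytes_per_snp = math.ceil(n / 4)
    if len(raw) - 3 != bytes_per_snp * p:
        raise PlinkCorruptError(
            f"{prefix}.bed payload is {len(raw) - 3} bytes; expected "
            f"{bytes_per_snp * p} for {n} samples x {p} SNPs"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (payload[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, -1)[:, :n]
    a1_counts = _CODE_TO_A1_COUNT[codes].T  # -> n x p
    dosages, flipped = _orient_to_minor(a1_counts)

    snps = bim[["snp_id", "chromosome", "position", "allele1", "allele2"]].copy()
    # after orientation the minor allele is allele1 unless the SNP was flipped
    minor = np.where(flipped, snps["allele2"], snps["allele1"])
    major = np.where(flipped, snps["allele1"], snps["allele2"])
    snps["minor_allele"] = minor
    snps["major_allele"] = major
    miss = dosages == MISSING
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        snps["maf"] = np.nanmean(np.where(miss, np.nan, dosages.astype(float)), axis=0) / 2.0

    pheno = fam["pheno_code"].map({1: 0, 2: 1}).astype("float")  # -9 and others -> NaN
    samples = pd.DataFrame({
        "sample_id": fam["sample_id"],
        "phenotype": pheno,
        "sex": fam["sex_code"].map({1: "male", 2: "female"}),
    })
    _validate_snp_table(snps)
    _validate_sample_table(samples)
    geno = GenotypeMatrix(dosages, samples["sample_id"].to_numpy(), snps["snp_id"].to_numpy())
    return geno, snps, samples


def write_plink(geno: GenotypeMatrix, snps: pd.DataFrame, samples: pd.DataFrame,
                prefix: str | Path) -> None:
    """Write a SNP-major PLINK binary fileset.

    Dosages are written counting allele1 copies on disk, so a minor-oriented
    matrix is stored with allele1 = minor allele (round-trips identically).
    """
    prefix = Path(prefix)
    if geno.n_snps != len(snps) or geno.n_samples != len(samples):
        raise ValueError(
            f"dimension mismatch: genotype {geno.dosages.shape}, "
            f"{len(snps)} SNPs, {len(samples)} samples"
        )
    _validate_snp_table(snps)
    _validate_sample_table(samples)

    n, p = geno.n_samples, geno.n_snps
    bytes_per_snp = math.ceil(n / 4)
    # dosage (minor-allele count) -> 2-bit code, treating allele1 as minor
    dos_to_code = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
    lut = np.zeros(256, dtype=np.uint8)
    for d, c in dos_to_code.items():
        lut[d & 0xFF] = c  # MISSING (-1) wraps to 255
    codes = lut[geno.dosages.T.view(np.uint8)]  # p x n
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    padded = padded.reshape(p, bytes_per_snp, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())

    bim = pd.DataFrame({
        "chromosome": snps["chromosome"], "snp_id": snps["snp_id"], "cm": 0,
        "position": snps["position"], "allele1": snps["allele1"], "allele2": snps["allele2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    sex_code = samples.get("sex", pd.Series(index=samples.index, dtype=object))
    sex_code = sex_code.map({"male": 1, "female": 2}).fillna(0).astype(int)
    pheno_code = samples["phenotype"].map({0: 1, 1: 2}).fillna(-9).astype(int)
    fam = pd.DataFrame({
        "fid": samples["sample_id"], "sample_id": samples["sample_id"],
        "pat": 0, "mat": 0, "sex_code": sex_code, "pheno_code": pheno_code,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_covariates(path: str | Path, samples: pd.DataFrame) -> pd.DataFrame:
    """Merge a delimited covariate table (sample_id, sex, neutered, weight) into the sample table.

    Covariate rows whose sample_id is absent from the fileset are dropped with
    a warning; fileset samples without covariates keep missing values.
    """
    cov = pd.read_csv(path, sep=None, engine="python", dtype={"sample_id": str})
    required = {"sample_id", "sex", "neutered", "weight"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"covariate file missing columns {sorted(missing)}")
    known = set(samples["sample_id"])
    unmatched = cov.loc[~cov["sample_id"].isin(known), "sample_id"]
    if len(unmatched):
        warnings.warn(
            f"dropping {len(unmatched)} covariate rows with unknown sample_id "
            f"(e.g. {unmatched.iloc[0]!r})"
        )
        cov = cov[cov["sample_id"].isin(known)]
    cov = cov.drop_duplicates("sample_id")
    merged = samples.drop(columns=[c for c in ("sex", "neutered", "weight") if c in samples],
                          errors="ignore")
    merged = merged.merge(cov[["sample_id", "sex", "neutered", "weight"]],
                          on="sample_id", how="left")
    if (merged["weight"].dropna() <= 0).any():
        raise ValueError("non-positive body weights in covariate file")
    return merged
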