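"""Marker QC filters, exact Hardy-Weinberg test and windowed LD pruning."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from gprisk import QCConfig, apply_qc, hwe_exact_p, ld_prune, snp_maf
from gprisk.io_plink import MISSING, mean_impute

from conftest import toy_tables


# --------------------------------------------------------------------- MAF


def test_maf_examples():
    geno, _, _ = toy_tables(np.array([[0, 2, 0], [0, 2, 1], [0, 2, 1], [0, 2, 2]]))
    maf = snp_maf(geno)
    assert maf[0] == 0.0
    assert maf[1] == 0.0          # folded: all-dosage-2 is the major allele
    assert maf[2] == 0.5          # 4 of 8 alleles


def test_maf_ignores_missing_calls():
    geno, _, _ = toy_tables(np.array([[1], [MISSING], [1], [MISSING]]))
    assert snp_maf(geno)[0] == 0.5


# --------------------------------------------------------------------- HWE


def hwe_oracle(n_hom1, n_het, n_hom2):
    """Direct enumeration of the conditional het distribution via log-factorials."""
    n = n_hom1 + n_het + n_hom2
    nr = 2 * min(n_hom1, n_hom2) + n_het
    hets = np.arange(nr % 2, nr + 1, 2)
    hr = (nr - hets) // 2
    hc = n - hets - hr
    logp = (gammaln(n + 1) - gammaln(hr + 1) - gammaln(hc + 1) - gammaln(hets + 1)
            + hets * np.log(2.0))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def test_hwe_monomorphic_is_one():
    assert hwe_exact_p(0, 0, 100) == 1.0
    assert hwe_exact_p(7, 0, 0) == 1.0


def test_hwe_matches_enumeration_oracle():
    assert hwe_exact_p(25, 50, 25) == pytest.approx(hwe_oracle(25, 50, 25), abs=1e-12)
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(1, 200))
        a = int(rng.integers(0, n + 1))
        b = int(rng.integers(0, n - a + 1))
        c = n - a - b
        assert hwe_exact_p(a, b, c) == pytest.approx(hwe_oracle(a, b, c), abs=1e-12)


def test_hwe_all_homozygote_split_fails_filter():
    assert hwe_exact_p(50, 0, 50) < 1e-7


def test_hwe_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact_p(-1, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact_p(0, 0, 0)


# --------------------------------------------------------------------- apply_qc


def build_filter_fixture():
    """Six SNPs: one trips each filter once, three survive."""
    rng = np.random.default_rng(2)
    n = 100
    good = rng.choice([0, 1, 2], size=(n, 3), p=[0.49, 0.42, 0.09])
    low_call = rng.choice([0, 1, 2], size=(n, 1))
    low_call[: n // 10] = MISSING                     # call rate 0.90 <= 0.95
    rare = np.zeros((n, 1), dtype=int)
    rare[:10] = 1                                     # MAF 0.05 (inclusive boundary)
    hwe_bad = np.array([0] * 50 + [2] * 50)[:, None]  # no hets at MAF 0.5
    dosages = np.hstack([low_call, rare, hwe_bad, good])
    return toy_tables(dosages)


def test_apply_qc_counts_and_order():
    geno, snps, _ = build_filter_fixture()
    filtered, fsnps, report = apply_qc(geno, snps)
    assert report.counts() == {"input": 6, "callrate": 1, "maf": 1, "hwe": 1,
                               "remaining": 3}
    assert report.removed_callrate == ["m0"]
    assert report.removed_maf == ["m1"]   # MAF exactly 0.05 removed (inclusive)
    assert report.removed_hwe == ["m2"]
    assert filtered.n_snps == 3 and len(fsnps) == 3


def test_apply_qc_idempotent():
    geno, snps, _ = build_filter_fixture()
    once, snps1, _ = apply_qc(geno, snps)
    twice, snps2, rep2 = apply_qc(once, snps1)
    np.testing.assert_array_equal(once.dosages, twice.dosages)
    assert rep2.counts()["remaining"] == rep2.counts()["input"]


def test_apply_qc_empty_result_warns():
    geno, snps, _ = toy_tables(np.zeros((20, 2), dtype=np.int8))  # monomorphic
    with pytest.warns(UserWarning, match="every SNP"):
        filtered, _, report = apply_qc(geno, snps)
    assert filtered.n_snps == 0 and report.n_remaining == 0


# --------------------------------------------------------------------- LD prune


def brute_force_prune(X, maf, pos, r2_max=0.7):
    """All-pairs greedy pruner over the full SNP set (no windows)."""
    alive = list(range(X.shape[1]))
    while True:
        best = None
        for a, b in itertools.combinations(alive, 2):
            xa, xb = X[:, a], X[:, b]
            if xa.std() == 0 or xb.std() == 0:
                continue
            r2 = np.corrcoef(xa, xb)[0, 1] ** 2
            if r2 > r2_max and (best is None or r2 > best[0]):
                best = (r2, a, b)
        if best is None:
            return alive
        _, a, b = best
        if maf[a] < maf[b]:
            drop = a
        elif maf[b] < maf[a]:
            drop = b
        else:
            drop = a if pos[a] > pos[b] else b
        alive.remove(drop)


def test_duplicate_column_pruned():
    rng = np.random.default_rng(1)
    col = rng.choice([0, 1, 2], size=(50, 1))
    other = rng.choice([0, 1, 2], size=(50, 1))
    geno, snps, _ = toy_tables(np.hstack([col, col, other]))
    kept = ld_prune(geno, snps)
    assert len(kept) == 2
    assert "m2" in kept


def test_independent_snps_all_kept(null_cohort):
    # take one SNP per block: mutually near-independent
    idx = np.arange(0, null_cohort.geno.n_snps, null_cohort.config.block_size)
    geno = null_cohort.geno.subset_snps(idx)
    snps = null_cohort.snps.iloc[idx].reset_index(drop=True)
    kept = ld_prune(geno, snps)
    assert len(kept) == geno.n_snps


def test_prune_matches_brute_force_on_planted_fixture():
    rng = np.random.default_rng(5)
    n = 120
    base = rng.choice([0, 1, 2], size=(n, 12), p=[0.36, 0.48, 0.16])
    # plant three highly correlated pairs
    for src, dst in [(0, 1), (4, 5), (8, 9)]:
        copy = base[:, src].copy()
        flip = rng.random(n) < 0.05
        copy[flip] = rng.choice([0, 1, 2], size=flip.sum())
        base[:, dst] = copy
    geno, snps, _ = toy_tables(base)
    X, _ = mean_impute(geno.dosages)
    kept = ld_prune(geno, snps)
    oracle = brute_force_prune(X, snp_maf(geno), snps["position"].to_numpy())
    assert sorted(kept) == sorted(geno.snp_ids[oracle])


def test_no_kept_pair_exceeds_threshold(small_cohort):
    cfg = QCConfig()
    kept = ld_prune(small_cohort.geno, small_cohort.snps, cfg)
    pos = {s: i for i, s in enumerate(small_cohort.geno.snp_ids)}
    idx = np.array([pos[s] for s in kept])
    X, _ = mean_impute(small_cohort.geno.dosages[:, idx])
    for start in range(0, len(idx) - 1, cfg.ld_step):
        win = X[:, start:start + cfg.ld_window]
        sd = win.std(axis=0)
        ok = sd > 0
        r2 = np.square(np.corrcoef(win[:, ok], rowvar=False))
        np.fill_diagonal(r2, 0.0)
        assert r2.max() <= cfg.ld_r2_max + 1e-12


def test_unsorted_snp_table_rejected(small_cohort):
    snps = small_cohort.snps.iloc[::-1].reset_index(drop=True)
    with pytest.raises(ValueError, match="not position-sorted"):
        ld_prune(small_cohort.geno, snps)
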