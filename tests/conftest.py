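import numpy as np
import pandas as pd
import pytest

from gprisk import GenotypeMatrix, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Moderately informative cohort reused across modules: blocky LD,
    polygenic signal, covariate effects, a little missingness."""
    cfg = SimConfig(n_individuals=300, n_snps=400, block_size=10, n_causal=40,
                    h2_liability=0.5, prevalence_K=0.3, missing_rate=0.02, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No genetic or covariate signal: labels independent of everything."""
    cfg = SimConfig(n_individuals=300, n_snps=200, n_causal=0, h2_liability=0.0,
                    covariate_effects=(0.0, 0.0, 0.0), prevalence_K=0.3,
                    missing_rate=0.0, seed=11)
    return simulate_cohort(cfg)


def toy_tables(dosages, sample_prefix="s", snp_prefix="m"):
    """Build a consistent (GenotypeMatrix, SNPTable, SampleTable) triple from
    a raw dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    sample_ids = np.array([f"{sample_prefix}{i}" for i in range(n)], dtype=object)
    snp_ids = np.array([f"{snp_prefix}{j}" for j in range(p)], dtype=object)
    geno = GenotypeMatrix(dosages, sample_ids, snp_ids)
    snps = pd.DataFrame({
        "snp_id": snp_ids, "chromosome": "1",
        "position": np.arange(1, p + 1) * 100,
        "allele1": "A", "allele2": "C",
    })
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "phenotype": (np.arange(n) % 2),
        "sex": np.where(np.arange(n) % 2 == 0, "female", "male"),
        "neutered": "intact",
        "weight": 30.0 + np.arange(n),
    })
    return geno, snps, samples
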