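import numpy as np
import pandas as pd
import pytest

from cohortpgs import CohortConfig, GenotypeMatrix, simulate_cohort


def make_geno(dosages, sample_ids=None, snp_ids=None, chrom=None, pos=None):
    """Small literal genotype matrix for fixtures."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j:03d}" for j in range(p)]
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom if chrom is not None else 1,
            "pos": pos if pos is not None else 100 * (1 + np.arange(p)),
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages=dosages, snps=snps, sample_ids=sample_ids)


def make_pheno(geno, heights, birth_year=1966, age=45.0, sex="male"):
    n = geno.n_samples
    return pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "sex": sex,
            "birth_year": np.broadcast_to(birth_year, n).copy(),
            "age": np.broadcast_to(age, n).astype(float).copy(),
            "height_cm": np.asarray(heights, dtype=float),
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One modest male cohort shared by read-only tests."""
    cfg = CohortConfig.for_sex(
        "male", n_samples=400, n_snps=150, n_causal=12, seed=20259
    )
    geno, pheno, truth = simulate_cohort(cfg)
    return cfg, geno, pheno, truth
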