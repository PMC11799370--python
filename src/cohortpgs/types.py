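"""Core in-memory containers shared by all pipeline stages.

Genotypes are held as a dense ``samples x SNPs`` dosage matrix of floats,
with ``NaN`` marking missing calls.  Dosage counts copies of the A1
(counted) allele recorded in the SNP metadata, so values are 0, 1, 2 or
missing.  Phenotypes travel as a plain :class:`pandas.DataFrame` with the
columns ``sample_id, sex, birth_year, age, height_cm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a phenotype table, in canonical order.
PHENO_COLUMNS = ["sample_id", "sex", "birth_year", "age", "height_cm"]


class ConfigError(ValueError):
    """A configuration value is outside its documented domain."""


class AlignmentError(ValueError):
    """Sample or SNP identifiers do not line up between two inputs."""


class PipelineError(RuntimeError):
    """A pipeline stage cannot proceed (e.g. empty SNP intersection)."""


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix plus SNP and sample metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array; entries in {0, 1, 2, NaN}.
    snps
        DataFrame with columns ``snp_id, chrom, pos, a1, a2`` (one row per
        SNP, in column order of ``dosages``).
    sample_ids
        Sample identifiers, in row order of ``dosages``.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise AlignmentError(
                f"{len(self.sample_ids)} sample ids for {n} genotype rows"
            )
        if len(self.snps) != p:
            raise AlignmentError(f"{len(self.snps)} SNP records for {p} columns")
        missing_cols = {"snp_id", "chrom", "pos", "a1", "a2"} - set(self.snps.columns)
        if missing_cols:
            raise ValueError(f"snps table missing columns: {sorted(missing_cols)}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    def sample_index(self, ids) -> np.ndarray:
        """Row indices of the given sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def snp_index(self, ids) -> np.ndarray:
        """Column indices of the given SNP ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.snps["snp_id"])}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise AlignmentError(f"unknown SNP ids: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def subset(self, sample_ids=None, snp_ids=None) -> "GenotypeMatrix":
        """New matrix restricted to the given samples and/or SNPs."""
        rows = (
            self.sample_index(sample_ids)
            if sample_ids is not None
            else np.arange(self.n_samples)
        )
        cols = (
            self.snp_index(snp_ids) if snp_ids is not None else np.arange(self.n_snps)
        )
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(rows, cols)],
            snps=self.snps.iloc[cols].reset_index(drop=True),
            sample_ids=[self.sample_ids[i] for i in rows],
        )


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check that a phenotype table has the canonical columns."""
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    return pheno


def align_samples(geno: GenotypeMatrix, pheno: pd.DataFrame) -> pd.DataFrame:
    """Return ``pheno`` reordered to match ``geno`` row order.

    Raises :class:`AlignmentError` listing offenders on mismatch.
    """
    validate_phenotypes(pheno)
    pheno_ids = set(pheno["sample_id"])
    geno_ids = set(geno.sample_ids)
    if pheno_ids != geno_ids:
        only_g = sorted(geno_ids - pheno_ids)[:5]
        only_p = sorted(pheno_ids - geno_ids)[:5]
        raise AlignmentError(
            f"sample id mismatch: genotype-only {only_g}, phenotype-only {only_p}"
        )
    return (
        pheno.set_index("sample_id").loc[geno.sample_ids].reset_index()
    )
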