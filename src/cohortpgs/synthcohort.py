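"""Seeded synthetic biobank cohorts for exercising the prediction pipeline.

The generator emulates the statistical structure of a Taiwanese
biobank-style cohort: an additive polygenic architecture for adult height
with sex-specific causal panels, a linear secular trend of height on birth
year (taller recent cohorts), an age-related height decline, genotype
missingness, a minor-allele-frequency spectrum, designated SNPs violating
Hardy-Weinberg equilibrium, and designated close-kin sample pairs — the
features the quality-control and modelling stages must detect or exploit.

Deterministic layout conventions (documented here, relied on by tests):

* HWE-violating SNPs occupy the **last** ``n_hwe_violators`` columns and
  are flagged in the SNP metadata column ``hwe_violator``.
* Related pairs occupy the **first** ``2 * n_related_pairs`` rows, as
  consecutive (parent, offspring) pairs; :func:`related_pairs` lists them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import ConfigError, GenotypeMatrix, PHENO_COLUMNS

#: Inbreeding-style excess-homozygosity coefficient for designated HWE
#: violators; large enough that the exact-test p-value is far below 1e-10
#: at any cohort size the pipeline is run at (chi-square ~ n * F^2).
_HWE_VIOLATOR_F = 0.6

# Cohort-level targets mirrored from the two source populations: mean and
# total SD of adult height (cm) and the fitted secular trend (cm per birth
# year) for each sex.
SEX_PRESETS = {
    "male": {"baseline_mean_cm": 169.47, "total_sd_cm": 6.29, "secular_slope": 0.2258},
    "female": {"baseline_mean_cm": 157.43, "total_sd_cm": 5.66, "secular_slope": 0.1890},
}


def _uniform_int_var(lo: int, hi: int) -> float:
    """Variance of a discrete uniform draw on the closed range [lo, hi]."""
    k = hi - lo + 1
    return (k * k - 1) / 12.0


@dataclass
class CohortConfig:
    """All knobs of one synthetic cohort; every stochastic draw is seeded.

    ``age_slope`` is the per-year height decline with age (typically
    negative); ``secular_slope`` the cm-per-birth-year secular trend.
    ``heritability_target`` is the fraction of total height variance
    contributed by the causal SNP panel.
    """

    n_samples: int = 5000
    n_snps: int = 2000
    n_causal: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    heritability_target: float = 0.45
    sex: str = "male"
    secular_slope: float = 0.2258
    age_slope: float = -0.05
    birth_year_range: tuple[int, int] = (1946, 1986)
    measurement_year_range: tuple[int, int] = (2005, 2020)
    baseline_mean_cm: float = 169.47
    residual_sd_cm: float = 3.34
    missing_rate: float = 0.02
    n_hwe_violators: int = 5
    n_related_pairs: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be positive")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be positive")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ConfigError("n_causal must satisfy 0 <= n_causal <= n_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.heritability_target < 1:
            raise ConfigError("heritability_target must lie in [0, 1)")
        if self.sex not in ("male", "female"):
            raise ConfigError("sex must be 'male' or 'female'")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ConfigError("birth_year_range must be (lo, hi) with lo <= hi")
        if self.measurement_year_range[0] > self.measurement_year_range[1]:
            raise ConfigError("measurement_year_range must be (lo, hi) with lo <= hi")
        if self.residual_sd_cm <= 0:
            raise ConfigError("residual_sd_cm must be positive")
        if self.n_hwe_violators < 0 or self.n_hwe_violators > self.n_snps:
            raise ConfigError("n_hwe_violators must lie in [0, n_snps]")
        if 2 * self.n_related_pairs > self.n_samples:
            raise ConfigError("n_related_pairs too large for n_samples")

    def environmental_variance(self) -> float:
        """Variance of the secular + age linear terms under the config.

        Birth year B and measurement year M are independent discrete
        uniforms; the covariate part is ``b*B + a*M`` (see
        :func:`simulate_phenotypes`), with variance
        ``b^2 Var(B) + a^2 Var(M)``.
        """
        v_b = _uniform_int_var(*self.birth_year_range)
        v_m = _uniform_int_var(*self.measurement_year_range)
        return self.secular_slope**2 * v_b + self.age_slope**2 * v_m

    @classmethod
    def for_sex(cls, sex: str, **overrides) -> "CohortConfig":
        """Preset config for one sex, with residual SD solved so the total
        height SD matches the cohort target for that sex."""
        preset = SEX_PRESETS[sex]
        cfg = cls(
            sex=sex,
            baseline_mean_cm=preset["baseline_mean_cm"],
            secular_slope=preset["secular_slope"],
            **overrides,
        )
        total_var = preset["total_sd_cm"] ** 2
        resid_var = total_var * (1 - cfg.heritability_target) - cfg.environmental_variance()
        if resid_var <= 0:
            raise ConfigError(
                "heritability_target and trend slopes exceed the total variance target"
            )
        return replace(cfg, residual_sd_cm=float(np.sqrt(resid_var)))


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort, for parameter-recovery tests."""

    causal_snp_ids: list[str]
    causal_betas: np.ndarray
    causal_freqs: np.ndarray
    secular_slope: float
    age_slope: float
    realized_h2: float
    genetic_component: np.ndarray = field(repr=False, default=None)


def related_pairs(config: CohortConfig) -> list[tuple[str, str]]:
    """(parent_id, offspring_id) pairs under the deterministic layout."""
    return [
        (_sample_id(2 * k), _sample_id(2 * k + 1))
        for k in range(config.n_related_pairs)
    ]


def _sample_id(i: int) -> str:
    return f"S{i:06d}"


def _snp_table(config: CohortConfig) -> pd.DataFrame:
    """SNP metadata: 22 autosomal blocks, positions increasing in column
    order so that position-sorted output equals column order."""
    n = config.n_snps
    chrom = 1 + (np.arange(n) * 22) // n
    pos = np.zeros(n, dtype=int)
    for c in range(1, 23):
        m = chrom == c
        pos[m] = 10_000 * (1 + np.arange(m.sum()))
    violator = np.zeros(n, dtype=bool)
    if config.n_hwe_violators:
        violator[-config.n_hwe_violators :] = True
    return pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(n)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "G",
            "hwe_violator": violator,
        }
    )


def simulate_genotypes(config: CohortConfig) -> GenotypeMatrix:
    """Draw the cohort's dosage matrix.

    Ordinary SNPs are in Hardy-Weinberg proportions: allele frequency
    ``p ~ Uniform(maf_range)`` and dosage ``Binomial(2, p)``.  Designated
    violator SNPs get excess homozygosity (inbreeding coefficient
    ``F = 0.6``).  Offspring of designated related pairs inherit one
    allele per locus from their parent (expected kinship 1/4).  Missing
    calls are inserted uniformly at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_snps

    freqs = rng.uniform(*config.maf_range, size=p)
    n_viol = config.n_hwe_violators
    if n_viol:
        # Violators need common alleles so all three genotype classes occur.
        freqs[-n_viol:] = rng.uniform(0.2, 0.5, size=n_viol)

    dosages = rng.binomial(2, freqs[None, :], size=(n, p)).astype(float)

    if n_viol:
        f = _HWE_VIOLATOR_F
        pv = freqs[-n_viol:]
        qv = 1 - pv
        probs = np.stack(  # genotype classes 0/1/2 for counted allele
            [qv * qv + f * pv * qv, 2 * pv * qv * (1 - f), pv * pv + f * pv * qv]
        ).T
        u = rng.random(size=(n, n_viol))
        cum = np.cumsum(probs, axis=1)
        dosages[:, -n_viol:] = (u[:, :, None] > cum[None, :, :-1]).sum(axis=2)

    for k in range(config.n_related_pairs):
        parent, child = 2 * k, 2 * k + 1
        transmitted = rng.random(p) < dosages[parent] / 2.0
        other = rng.random(p) < freqs
        dosages[child] = transmitted.astype(float) + other.astype(float)

    if config.missing_rate > 0:
        mask = rng.random(size=(n, p)) < config.missing_rate
        dosages[mask] = np.nan

    return GenotypeMatrix(
        dosages=dosages,
        snps=_snp_table(config),
        sample_ids=[_sample_id(i) for i in range(n)],
    )


def simulate_phenotypes(
    geno: GenotypeMatrix, config: CohortConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw heights on top of a genotype matrix from the same config.

    height = baseline + b*(birth_year - mean) + a*(meas_year - mean)
             + sum_j beta_j * (g_j - 2 p_j) + eps,   eps ~ N(0, residual_sd)

    Because age = meas_year - birth_year, the measurement-year term is the
    age effect *conditional on birth cohort*: within a birth year, being
    measured ``d`` years later (hence ``d`` years older) shifts height by
    ``a * d``.  Writing the model this way makes ``secular_slope`` equal
    the cohort's observable mean-height-on-birth-year trendline slope
    (the two year variables are independent draws); the naive form
    ``b*birth_year + a*age`` would instead show a marginal trend of
    ``b - a``, since age and birth year are nearly collinear.

    Causal effects are drawn N(0, 1) on the counted-allele dosage scale and
    rescaled as a block so the genetic variance fraction of total height
    variance hits ``heritability_target`` (realized fraction recorded in
    the returned :class:`TruthRecord`).  Missing dosages contribute their
    SNP's observed mean dosage to the genetic term.
    """
    config.validate()
    if geno.n_samples != config.n_samples or geno.n_snps != config.n_snps:
        raise ConfigError("genotype matrix shape does not match config")
    # Offset the seed stream so phenotype noise is independent of the
    # genotype draws yet still fully determined by config.seed.
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = config.n_samples

    birth_year = rng.integers(
        config.birth_year_range[0], config.birth_year_range[1] + 1, size=n
    )
    meas_year = rng.integers(
        config.measurement_year_range[0], config.measurement_year_range[1] + 1, size=n
    )
    age = (meas_year - birth_year).astype(float)

    env = (
        config.secular_slope * (birth_year - birth_year.mean())
        + config.age_slope * (meas_year - meas_year.mean())
        + rng.normal(0.0, config.residual_sd_cm, size=n)
    )

    candidates = np.flatnonzero(~geno.snps["hwe_violator"].to_numpy())
    causal_idx = np.sort(rng.choice(candidates, size=config.n_causal, replace=False))
    betas = rng.normal(0.0, 1.0, size=config.n_causal)

    dos = geno.dosages[:, causal_idx]
    col_mean = np.nanmean(dos, axis=0)
    dos_filled = np.where(np.isnan(dos), col_mean[None, :], dos)
    freqs = col_mean / 2.0  # realized counted-allele frequency
    centered = dos_filled - 2.0 * freqs[None, :]

    genetic = centered @ betas
    h2 = config.heritability_target
    if h2 > 0 and genetic.var() > 0:
        scale = np.sqrt(h2 / (1 - h2) * env.var() / genetic.var())
    else:
        scale = 0.0
    betas = betas * scale
    genetic = genetic * scale

    height = config.baseline_mean_cm + env + genetic
    total_var = height.var()
    realized_h2 = float(genetic.var() / total_var) if total_var > 0 else 0.0

    pheno = pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "sex": config.sex,
            "birth_year": birth_year,
            "age": age,
            "height_cm": height,
        }
    )[PHENO_COLUMNS]

    truth = TruthRecord(
        causal_snp_ids=[geno.snps["snp_id"].iat[j] for j in causal_idx],
        causal_betas=betas,
        causal_freqs=freqs,
        secular_slope=config.secular_slope,
        age_slope=config.age_slope,
        realized_h2=realized_h2,
        genetic_component=genetic,
    )
    return pheno, truth


def simulate_cohort(
    config: CohortConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Convenience wrapper: genotypes and phenotypes in one call."""
    geno = simulate_genotypes(config)
    pheno, truth = simulate_phenotypes(geno, config)
    return geno, pheno, truth


def simulate_validation_cohort(
    config: CohortConfig, truth: TruthRecord, seed: int
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """An independent cohort drawn from the *same* population.

    Genotypes, year draws and noise are fresh (driven by ``seed``), but
    the causal SNPs and their effect sizes are taken verbatim from the
    training cohort's :class:`TruthRecord` — the situation of an external
    validation cohort genotyped on the same array: same architecture,
    different individuals.  Allele frequencies are re-drawn, so realized
    heritability differs slightly from the training cohort's.
    """
    cfg = replace(config, seed=seed)
    geno = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1_000_003)
    n = cfg.n_samples

    birth_year = rng.integers(
        cfg.birth_year_range[0], cfg.birth_year_range[1] + 1, size=n
    )
    meas_year = rng.integers(
        cfg.measurement_year_range[0], cfg.measurement_year_range[1] + 1, size=n
    )
    age = (meas_year - birth_year).astype(float)
    env = (
        cfg.secular_slope * (birth_year - birth_year.mean())
        + cfg.age_slope * (meas_year - meas_year.mean())
        + rng.normal(0.0, cfg.residual_sd_cm, size=n)
    )

    cols = geno.snp_index(truth.causal_snp_ids)
    dos = geno.dosages[:, cols]
    col_mean = np.nanmean(dos, axis=0)
    dos_filled = np.where(np.isnan(dos), col_mean[None, :], dos)
    genetic = (dos_filled - col_mean[None, :]) @ truth.causal_betas

    height = cfg.baseline_mean_cm + env + genetic
    pheno = pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "sex": cfg.sex,
            "birth_year": birth_year,
            "age": age,
            "height_cm": height,
        }
    )[PHENO_COLUMNS]
    val_truth = TruthRecord(
        causal_snp_ids=list(truth.causal_snp_ids),
        causal_betas=truth.causal_betas.copy(),
        causal_freqs=col_mean / 2.0,
        secular_slope=cfg.secular_slope,
        age_slope=cfg.age_slope,
        realized_h2=float(genetic.var() / height.var()),
        genetic_component=genetic,
    )
    return geno, pheno, val_truth
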