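"""Single-SNP association: OLS of height on additive allele dosage.

Each SNP is tested on its own (height ~ intercept + dosage), complete
cases only, with the two-sided p-value from the t distribution on n - 2
degrees of freedom.  ``run_gwas`` evaluates all SNPs at once from the
per-SNP sufficient statistics, so the genome-wide scan is a handful of
matrix products rather than a Python loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, PipelineError, align_samples


class SnpRegression(NamedTuple):
    beta: float
    se: float
    t: float
    p: float
    n: int


@dataclass
class GWASResult:
    """Per-SNP OLS summary; degenerate SNPs carry NaN beta/se/t/p."""

    table: pd.DataFrame  # snp_id chrom pos beta se t p n

    def pvalues(self) -> pd.Series:
        return self.table.set_index("snp_id")["p"]


def single_snp_regression(heights, dosages) -> SnpRegression:
    """OLS of height on one SNP's dosage, complete cases only.

    Returns NaN statistics (n still reported) when fewer than 3 complete
    pairs remain or the dosage is constant among them.
    """
    y = np.asarray(heights, dtype=float)
    x = np.asarray(dosages, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.ptp(x) == 0:
        return SnpRegression(np.nan, np.nan, np.nan, np.nan, n)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    beta = sxy / sxx
    rss = syy - beta * sxy
    sigma2 = max(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    if se == 0:  # perfect fit
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return SnpRegression(float(beta), float(se), float(t), float(min(p, 1.0)), int(n))


def run_gwas(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    sample_subset=None,
) -> GWASResult:
    """Association scan of all SNPs restricted to ``sample_subset``.

    Per-SNP complete cases: a sample missing at SNP j is dropped for SNP j
    only.  Output row order matches the input SNP order.
    """
    pheno = align_samples(geno, pheno)
    if sample_subset is not None:
        ids = list(sample_subset)
        if not ids:
            raise PipelineError("empty sample subset for GWAS")
        rows = geno.sample_index(ids)
    else:
        rows = np.arange(geno.n_samples)

    g = geno.dosages[rows]
    y = pheno["height_cm"].to_numpy(dtype=float)[rows]
    return GWASResult(table=_table_from_stats(geno, *_suff_stats(g, y)))


def _suff_stats(g: np.ndarray, y: np.ndarray):
    """Per-SNP sufficient statistics (n, Sx, Sxx, Sy, Syy, Sxy) over the
    non-missing entries of each column."""
    valid = ~np.isnan(g)
    gz = np.where(valid, g, 0.0)
    v = valid.astype(float)
    return (
        v.sum(axis=0),
        gz.sum(axis=0),
        (gz * gz).sum(axis=0),
        y @ v,
        (y * y) @ v,
        y @ gz,
    )


def _table_from_stats(geno: GenotypeMatrix, n, sx, sxx, sy, syy, sxy) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_c = sxx - sx * sx / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy * sy / n
        beta = sxy_c / sxx_c
        rss = np.maximum(syy_c - beta * sxy_c, 0.0)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx_c)
        t = beta / se
        df = np.maximum(n - 2, 1)
        p = 2.0 * stats.t.sf(np.abs(t), df)

    bad = (n < 3) | ~(sxx_c > 1e-12)
    for arr in (beta, se, t, p):
        arr[bad] = np.nan

    table = geno.snps[["snp_id", "chrom", "pos"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["t"] = t
    table["p"] = np.minimum(p, 1.0)
    table["n"] = n.astype(int)
    return table


def run_gwas_folds(geno: GenotypeMatrix, pheno: pd.DataFrame, folds) -> list[GWASResult]:
    """Training-set GWAS for every fold at once.

    Exploits that fold f's training set is the complement of its test
    fold: per-SNP sufficient statistics are computed once for the whole
    cohort and once per (small) test fold, and subtracted.  Numerically
    identical to calling :func:`run_gwas` per fold.
    """
    pheno = align_samples(geno, pheno)
    y = pheno["height_cm"].to_numpy(dtype=float)
    totals = _suff_stats(geno.dosages, y)
    out = []
    for f in range(1, folds.k + 1):
        rows = geno.sample_index(folds.test_ids(f))
        test = _suff_stats(geno.dosages[rows], y[rows])
        train = tuple(tot - te for tot, te in zip(totals, test))
        out.append(GWASResult(table=_table_from_stats(geno, *train)))
    return out
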