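"""Prediction-weight fitting and ensemble height prediction.

For each covariate combination (PGS only, PGS + birth year, PGS + age,
PGS + birth year + age) one joint ordinary-least-squares fit regresses
height on all panel SNP dosages plus the covariates (plus optional
principal components), per training fold.  Prediction averages the K
fold models.  Missing dosages are mean-imputed with the *training* fold's
SNP means, both at fit and at prediction time, so no target-cohort
statistics leak into predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
import scipy.linalg

from .panel import SnpPanel
from .types import AlignmentError, GenotypeMatrix, align_samples

logger = logging.getLogger(__name__)

#: covariate columns per combination label
COMBINATIONS = {
    "PGS": (),
    "PGS+YEAR": ("birth_year",),
    "PGS+AGE": ("age",),
    "PGS+YEAR+AGE": ("birth_year", "age"),
}


@dataclass
class PcBasis:
    """Principal-component basis of the standardized training genotypes."""

    snp_ids: list[str]
    loadings: np.ndarray  # (n_snps, n_pcs), orthonormal columns
    eigenvalues: np.ndarray  # full spectrum, non-increasing
    means: np.ndarray  # training per-SNP mean dosage
    scales: np.ndarray  # training per-SNP dosage SD
    kaiser_count: int  # eigenvalues > 1

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]

    def project(self, geno: GenotypeMatrix) -> np.ndarray:
        """PC scores of (possibly new) samples using training statistics."""
        return self.project_rows(geno, np.arange(geno.n_samples))

    def project_rows(self, geno: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
        cols = geno.snp_index(self.snp_ids)
        x = geno.dosages[np.ix_(rows, cols)]
        x = np.where(np.isnan(x), self.means[None, :], x)
        xs = (x - self.means[None, :]) / self.scales[None, :]
        return xs @ self.loadings


@dataclass
class WeightSet:
    """Fitted weights of one fold model for one covariate combination."""

    combination: str
    fold: int
    intercept: float
    snp_ids: list[str]
    snp_weights: np.ndarray  # cm per counted allele, raw dosage scale
    snp_means: np.ndarray  # training-fold mean dosages (imputation values)
    covar_weights: dict[str, float] = field(default_factory=dict)
    pc_weights: np.ndarray | None = None
    pc_basis: PcBasis | None = None


def _design_matrix(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    snp_ids: list[str],
    covars: tuple[str, ...],
    snp_means: np.ndarray | None,
    pc_basis: PcBasis | None,
    rows: np.ndarray | None = None,
):
    """Assemble [SNP dosages | covariates | PCs] for the given sample rows
    (``pheno`` already restricted to them); returns (X, snp_means)."""
    if rows is None:
        rows = np.arange(geno.n_samples)
    cols = geno.snp_index(snp_ids)
    x = geno.dosages[np.ix_(rows, cols)]
    if snp_means is None:
        snp_means = np.nanmean(x, axis=0)
        snp_means = np.where(np.isnan(snp_means), 0.0, snp_means)
    x = np.where(np.isnan(x), snp_means[None, :], x)
    blocks = [x]
    for c in covars:
        blocks.append(pheno[c].to_numpy(dtype=float)[:, None])
    if pc_basis is not None:
        blocks.append(pc_basis.project_rows(geno, rows))
    return np.hstack(blocks), snp_means


def _ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS with intercept; rank-deficient columns are dropped (weight 0)."""
    n, p = design.shape
    a = np.hstack([np.ones((n, 1)), design])
    q, r, piv = scipy.linalg.qr(a, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(a.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < a.shape[1]:
        keep = np.sort(piv[:rank])
        logger.warning(
            "design matrix rank-deficient (rank %d of %d); dropping %d columns",
            rank, a.shape[1], a.shape[1] - rank,
        )
        coef = np.zeros(a.shape[1])
        coef[keep], *_ = np.linalg.lstsq(a[:, keep], y, rcond=None)
        return coef
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    return coef


def fit_weights(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    panel: SnpPanel,
    training_ids,
    combination: str = "PGS+YEAR+AGE",
    pc_basis: PcBasis | None = None,
    fold: int = 0,
) -> WeightSet:
    """One joint OLS fit of height on the panel SNPs plus covariates."""
    if combination not in COMBINATIONS:
        raise ValueError(f"unknown combination {combination!r}")
    if not panel.final_ids:
        raise ValueError("panel has no selected SNPs")
    pheno = align_samples(geno, pheno)
    rows = geno.sample_index(list(training_ids))
    sub_p = pheno.iloc[rows]

    covars = COMBINATIONS[combination]
    design, snp_means = _design_matrix(
        geno, sub_p, panel.final_ids, covars, None, pc_basis, rows=rows
    )
    y = sub_p["height_cm"].to_numpy(dtype=float)
    coef = _ols(design, y)

    k = len(panel.final_ids)
    ws = WeightSet(
        combination=combination,
        fold=fold,
        intercept=float(coef[0]),
        snp_ids=list(panel.final_ids),
        snp_weights=coef[1 : 1 + k],
        snp_means=snp_means,
        covar_weights={c: float(coef[1 + k + i]) for i, c in enumerate(covars)},
    )
    if pc_basis is not None:
        ws.pc_weights = coef[1 + k + len(covars) :]
        ws.pc_basis = pc_basis
    return ws


def predict(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    weight_sets: list[WeightSet],
    target_ids=None,
) -> pd.Series:
    """Ensemble prediction: arithmetic mean of the K fold models.

    Raises if any panel SNP is absent from the genotype data.
    """
    if not weight_sets:
        raise ValueError("no weight sets supplied")
    labels = {w.combination for w in weight_sets}
    if len(labels) > 1:
        raise ValueError(f"mixed covariate combinations: {sorted(labels)}")
    pheno = align_samples(geno, pheno)
    if target_ids is not None:
        rows = geno.sample_index(list(target_ids))
    else:
        rows = np.arange(geno.n_samples)
    pheno = pheno.iloc[rows]
    out_ids = [geno.sample_ids[i] for i in rows]

    missing = set(weight_sets[0].snp_ids) - set(geno.snps["snp_id"])
    if missing:
        raise AlignmentError(
            f"panel SNPs absent from genotype data: {sorted(missing)[:5]}"
        )

    total = np.zeros(rows.size)
    for ws in weight_sets:
        design, _ = _design_matrix(
            geno, pheno, ws.snp_ids, tuple(ws.covar_weights), ws.snp_means,
            ws.pc_basis, rows=rows,
        )
        coef = np.concatenate(
            [
                ws.snp_weights,
                np.array([ws.covar_weights[c] for c in ws.covar_weights]),
                ws.pc_weights if ws.pc_weights is not None else [],
            ]
        )
        total += ws.intercept + design @ coef
    return pd.Series(
        total / len(weight_sets), index=pd.Index(out_ids, name="sample_id")
    )


def pca_fit(
    geno: GenotypeMatrix, training_ids=None, n_pcs: int = 20
) -> PcBasis:
    """PCA of the standardized training genotype matrix.

    Eigenvalues are those of the SNP correlation matrix, so the Kaiser
    rule (eigenvalue > 1) applies; the count is reported but the number
    of returned components stays ``n_pcs`` (rank-limited with a warning).
    """
    if training_ids is not None:
        geno = geno.subset(sample_ids=list(training_ids))
    x = geno.dosages
    means = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), means[None, :], x)
    scales = x.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)  # constant SNPs contribute 0
    xs = (x - means[None, :]) / scales[None, :]

    _, s, vt = np.linalg.svd(xs, full_matrices=False)
    eig = s**2 / max(geno.n_samples - 1, 1)
    rank = int((s > s[0] * max(xs.shape) * np.finfo(float).eps).sum()) if s.size else 0
    if n_pcs > rank:
        logger.warning("n_pcs=%d exceeds rank %d; returning rank-limited basis",
                       n_pcs, rank)
        n_pcs = rank
    return PcBasis(
        snp_ids=geno.snp_ids,
        loadings=vt[:n_pcs].T,
        eigenvalues=eig,
        means=means,
        scales=scales,
        kaiser_count=int((eig > 1.0).sum()),
    )


def vif(design_columns: np.ndarray, names: list[str] | None = None) -> pd.Series:
    """Variance inflation factor of each column.

    VIF_j = 1 / (1 - R2_j), with R2_j from regressing column j on all the
    other columns (with intercept).  Perfect collinearity gives inf.
    """
    x = np.asarray(design_columns, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a matrix with at least two columns")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("columns must be non-constant")
    p = x.shape[1]
    out = np.empty(p)
    for j in range(p):
        yj = x[:, j]
        others = np.hstack(
            [np.ones((x.shape[0], 1)), np.delete(x, j, axis=1)]
        )
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - resid @ resid / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    index = names if names is not None else [f"col{j}" for j in range(p)]
    return pd.Series(out, index=index, name="vif")
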