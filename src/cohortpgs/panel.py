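"""SNP panel construction by cross-validated selection.

The cohort is split into K folds (default 10).  For each fold's training
set a genome-wide scan supplies per-SNP p-values; only SNPs reaching
p <= alpha in *every* training set survive as candidates.  Each training
set then runs an L1-regularized (LASSO) selection traced with least-angle
regression, advancing along the path while the training R-squared still
improves by more than a tolerance; the final panel is the intersection of
the K selected sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from sklearn.linear_model import lars_path as _sk_lars_path

from .assoc import GWASResult
from .types import AlignmentError, ConfigError

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """Partition of samples into K folds of near-equal size (diff <= 1)."""

    labels: pd.Series  # index sample_id -> fold in 1..K
    k: int
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return self.labels.index[self.labels == fold].tolist()

    def training_ids(self, fold: int) -> list[str]:
        return self.labels.index[self.labels != fold].tolist()


@dataclass
class PathStep:
    """One LARS-LASSO breakpoint: active set, coefficients, training R^2."""

    active_ids: list[str]
    coefs: np.ndarray  # on the standardized-predictor scale
    r2: float
    alpha: float


@dataclass
class LarsPathResult:
    snp_ids: list[str]  # candidate columns actually used (post variance screen)
    steps: list[PathStep]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float


@dataclass
class SnpPanel:
    """Selected SNP panel with per-fold provenance."""

    candidate_ids: list[str]
    per_fold_sets: list[set[str]]
    final_ids: list[str]
    stop_steps: list[int] = field(default_factory=list)
    r2_traces: list[list[float]] = field(default_factory=list)


def make_folds(sample_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Uniformly random K-fold partition, reproducible by seed."""
    ids = list(sample_ids)
    n = len(ids)
    if k < 2:
        raise ConfigError("k must be at least 2")
    if n < k:
        raise ConfigError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    # Round-robin over the shuffled order: fold sizes differ by at most 1.
    labels[order] = 1 + np.arange(n) % k
    return FoldAssignment(
        labels=pd.Series(labels, index=pd.Index(ids, name="sample_id")),
        k=k,
        seed=seed,
    )


def pvalue_intersection_filter(
    gwas_by_fold: list[GWASResult], alpha: float = 0.05
) -> list[str]:
    """SNPs with p <= alpha in every fold's training-set scan.

    NaN p-values (degenerate SNPs) count as failing.  The returned list
    preserves the input SNP order.
    """
    if not gwas_by_fold:
        raise ConfigError("at least one GWAS result required")
    ref_ids = gwas_by_fold[0].table["snp_id"].tolist()
    keep = np.ones(len(ref_ids), dtype=bool)
    for res in gwas_by_fold:
        ids = res.table["snp_id"].tolist()
        if ids != ref_ids:
            raise AlignmentError("GWAS results cover different SNP sets")
        p = res.table["p"].to_numpy()
        keep &= ~np.isnan(p) & (p <= alpha)
    return [s for s, k in zip(ref_ids, keep) if k]


def lars_path(
    heights,
    dosages: np.ndarray,
    snp_ids: list[str],
    max_steps: int = 500,
) -> LarsPathResult:
    """LASSO solution path over candidate SNPs via least-angle regression.

    Candidates are mean-imputed, then standardized with training-sample
    statistics; heights are centered.  Zero-variance candidates (after
    imputation) are dropped with a warning.  Each breakpoint records the
    active set, standardized coefficients and training R-squared.
    """
    y = np.asarray(heights, dtype=float)
    x = np.asarray(dosages, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("dosages must be (n_samples, n_candidates)")

    col_mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_mean[None, :], x)
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    ok = scale > 0
    if not ok.all():
        dropped = [s for s, good in zip(snp_ids, ok) if not good]
        logger.warning("dropping %d zero-variance candidates: %s",
                       len(dropped), dropped[:5])
    kept_ids = [s for s, good in zip(snp_ids, ok) if good]
    xs = (x[:, ok] - mean[ok]) / scale[ok]
    y_mean = float(y.mean())
    yc = y - y_mean

    if not kept_ids:
        return LarsPathResult(kept_ids, [], mean[ok], scale[ok], y_mean)

    alphas, _, coefs = _sk_lars_path(xs, yc, method="lasso", max_iter=max_steps)
    tss = float(yc @ yc)
    steps = []
    for s in range(coefs.shape[1]):
        c = coefs[:, s]
        active = np.flatnonzero(c)
        resid = yc - xs @ c
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
        steps.append(
            PathStep(
                active_ids=[kept_ids[j] for j in active],
                coefs=c.copy(),
                r2=r2,
                alpha=float(alphas[s]),
            )
        )
    return LarsPathResult(kept_ids, steps, mean[ok], scale[ok], y_mean)


def select_snps(
    path: LarsPathResult,
    r2_tolerance: float = 1e-4,
    max_steps: int | None = None,
) -> set[str]:
    """Walk the path in R-squared order; stop at the first step whose gain
    over the previous step falls below ``r2_tolerance`` (or at
    ``max_steps``), returning the active set at the stopping step."""
    steps = path.steps
    if max_steps is not None:
        steps = steps[: max_steps + 1]
    if not steps:
        return set()
    stop = len(steps) - 1
    for s in range(1, len(steps)):
        if steps[s].r2 - steps[s - 1].r2 < r2_tolerance:
            stop = s - 1
            break
    return set(steps[stop].active_ids)


def intersect_selections(
    per_fold_sets: list[set[str]], snps: pd.DataFrame | None = None
) -> list[str]:
    """Exact intersection of the K per-fold selections.

    Sorted by genomic position when a SNP metadata table (``snp_id,
    chrom, pos``) is supplied, lexicographically otherwise.  An empty
    intersection is allowed but logged prominently.
    """
    if not per_fold_sets:
        raise ConfigError("no per-fold selections supplied")
    final = set.intersection(*map(set, per_fold_sets))
    if not final:
        logger.warning("SNP panel intersection across folds is EMPTY")
        return []
    if snps is not None:
        order = snps.set_index("snp_id").loc[list(final)][["chrom", "pos"]]
        return order.sort_values(["chrom", "pos"]).index.tolist()
    return sorted(final)
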