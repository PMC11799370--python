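"""End-to-end orchestration: QC -> folds -> fold-wise GWAS -> p-value
intersection -> fold-wise LASSO -> panel intersection -> weight fits ->
ensemble predictions -> metric reports.

Semantics of the three evaluation cohorts:

* *training*: each fold model predicts its own training samples; the K
  fold-wise prediction sets are pooled (n_reported = K * (K-1)/K * n).
* *testing*: every sample is predicted by all K fold models and the
  predictions averaged.  Because each sample sits inside K-1 of those
  models' training sets, this figure is optimistic — the reason an
  external validation cohort exists.
* *validation*: the same K-model average applied with frozen weights to
  an independent cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, evalmetrics, model, panel as panel_mod, plinkio, qc
from .types import ConfigError, GenotypeMatrix, PipelineError, align_samples

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and switches of one pipeline run (one sex stratum)."""

    # input paths (optional: the in-memory entry point bypasses them)
    genotype_path: str | None = None
    phenotype_path: str | None = None
    genotype_dialect: str = "plink_bed"
    validation_genotype_path: str | None = None
    validation_phenotype_path: str | None = None
    output_dir: str | None = None
    # QC thresholds
    miss_threshold: float = 0.1
    birth_window: tuple[int, int] = (1946, 1986)
    call_rate_min: float = 0.9
    maf_min: float = 0.01
    hwe_min_p: float = 1e-8
    kinship_threshold: float = qc.KINSHIP_3RD_DEGREE
    kinship: bool = True
    # cross-validation and selection
    k: int = 10
    alpha: float = 0.05
    r2_tolerance: float = 1e-4
    max_steps: int = 500
    # modelling
    combinations: tuple[str, ...] = ("PGS", "PGS+YEAR", "PGS+AGE", "PGS+YEAR+AGE")
    pca: bool = False
    n_pcs: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.k < 2:
            raise ConfigError("k must be at least 2")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must lie in (0, 1]")
        for name in ("miss_threshold", "call_rate_min", "maf_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not 0 < self.hwe_min_p <= 1:
            raise ConfigError("hwe_min_p must lie in (0, 1]")
        unknown = set(self.combinations) - set(model.COMBINATIONS)
        if unknown:
            raise ConfigError(f"unknown combinations: {sorted(unknown)}")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so the same
        analysis written to two directories shares a manifest)."""
        payload = asdict(self)
        for key in list(payload):
            if key.endswith("_path") or key == "output_dir":
                payload.pop(key)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PredictionReport:
    """Everything the pipeline produces for one sex stratum."""

    config: PipelineConfig
    folds: panel_mod.FoldAssignment
    candidate_ids: list[str]
    panel: panel_mod.SnpPanel
    weights: dict[str, list[model.WeightSet]]
    predictions: dict[tuple[str, str], pd.Series]  # (cohort, combination)
    metrics: dict[str, dict[str, evalmetrics.MetricReport]]
    manifest: dict = field(default_factory=dict)


def _apply_qc(
    geno: GenotypeMatrix, pheno: pd.DataFrame, config: PipelineConfig, label: str
) -> tuple[GenotypeMatrix, pd.DataFrame, qc.SnpQCReport, dict]:
    """Sample miss-rate/birth-year QC, then SNP QC, then kinship."""
    counts = {"samples_in": geno.n_samples, "snps_in": geno.n_snps}
    s_report = qc.sample_qc(geno, pheno, config.miss_threshold, config.birth_window)
    geno = geno.subset(sample_ids=s_report.passing_ids)
    counts["samples_after_missrate"] = geno.n_samples

    snp_report = qc.snp_qc(geno, config.call_rate_min, config.maf_min,
                           config.hwe_min_p)
    geno = geno.subset(snp_ids=snp_report.passing_ids)
    counts["snps_after_qc"] = geno.n_snps

    if config.kinship and geno.n_samples >= 2:
        k_report = qc.kinship_filter(geno, config.kinship_threshold)
        geno = geno.subset(sample_ids=k_report.passing_ids)
    counts["samples_after_kinship"] = geno.n_samples

    pheno = align_samples(geno, pheno[pheno["sample_id"].isin(set(geno.sample_ids))])
    logger.info("%s QC: %s", label, counts)
    return geno, pheno, snp_report, counts


def run_pipeline_data(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    config: PipelineConfig,
    val_geno: GenotypeMatrix | None = None,
    val_pheno: pd.DataFrame | None = None,
) -> PredictionReport:
    """Run the full pipeline on in-memory cohorts."""
    config.validate()
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": {}}

    geno, pheno, snp_report, counts = _apply_qc(geno, pheno, config, "training")
    manifest["stages"]["qc_training"] = counts

    if val_geno is not None:
        if val_pheno is None:
            raise ConfigError("validation genotypes supplied without phenotypes")
        val_geno, val_pheno, val_snp_report, vcounts = _apply_qc(
            val_geno, val_pheno, config, "validation"
        )
        manifest["stages"]["qc_validation"] = vcounts
        common = qc.intersect_snps(snp_report, val_snp_report)
        common = [s for s in common if s in set(geno.snps["snp_id"])]
        geno = geno.subset(snp_ids=common)
        val_geno = val_geno.subset(snp_ids=common)
        manifest["stages"]["snp_intersection"] = {"common_snps": len(common)}

    folds = panel_mod.make_folds(geno.sample_ids, config.k, config.seed)

    gwas_by_fold = assoc.run_gwas_folds(geno, pheno, folds)
    candidates = panel_mod.pvalue_intersection_filter(gwas_by_fold, config.alpha)
    manifest["stages"]["pvalue_intersection"] = {"candidates": len(candidates)}
    if not candidates:
        raise PipelineError("no SNP passed the fold-wise p-value intersection")

    # candidate columns ordered by genomic position (deterministic ties)
    cand_meta = geno.snps.set_index("snp_id").loc[candidates]
    candidates = cand_meta.sort_values(["chrom", "pos"]).index.tolist()
    cand_cols = geno.snp_index(candidates)
    y_all = pheno["height_cm"].to_numpy(dtype=float)

    per_fold_sets, stop_steps, traces = [], [], []
    for f in range(1, config.k + 1):
        rows = geno.sample_index(folds.training_ids(f))
        path = panel_mod.lars_path(
            y_all[rows], geno.dosages[np.ix_(rows, cand_cols)], candidates,
            max_steps=config.max_steps,
        )
        selected = panel_mod.select_snps(path, config.r2_tolerance, config.max_steps)
        per_fold_sets.append(selected)
        stop_steps.append(len(selected))
        traces.append([s.r2 for s in path.steps])

    final_ids = panel_mod.intersect_selections(per_fold_sets, geno.snps)
    snp_panel = panel_mod.SnpPanel(
        candidate_ids=candidates,
        per_fold_sets=per_fold_sets,
        final_ids=final_ids,
        stop_steps=stop_steps,
        r2_traces=traces,
    )
    manifest["stages"]["panel"] = {
        "per_fold_sizes": [len(s) for s in per_fold_sets],
        "final_size": len(final_ids),
    }
    if not final_ids:
        raise PipelineError("fold-wise LASSO selections share no SNP")

    pc_basis = (
        model.pca_fit(geno, n_pcs=config.n_pcs) if config.pca else None
    )
    if pc_basis is not None:
        manifest["stages"]["pca"] = {"kaiser_count": pc_basis.kaiser_count}

    weights: dict[str, list[model.WeightSet]] = {}
    for combo in config.combinations:
        weights[combo] = [
            model.fit_weights(
                geno, pheno, snp_panel, folds.training_ids(f), combo,
                pc_basis=pc_basis, fold=f,
            )
            for f in range(1, config.k + 1)
        ]

    predictions: dict[tuple[str, str], pd.Series] = {}
    metrics: dict[str, dict[str, evalmetrics.MetricReport]] = {
        "training": {}, "testing": {},
    }
    actual = pd.Series(y_all, index=pd.Index(geno.sample_ids, name="sample_id"))
    for combo in config.combinations:
        # training: pool each fold model's in-sample predictions
        pooled_pred, pooled_act = [], []
        for f, ws in enumerate(weights[combo], start=1):
            ids = folds.training_ids(f)
            pred_f = model.predict(geno, pheno, [ws], target_ids=ids)
            pooled_pred.append(pred_f)
            pooled_act.append(actual.loc[ids])
        predictions[("training", combo)] = pd.concat(pooled_pred)
        metrics["training"][combo] = evalmetrics.evaluate(
            pd.concat(pooled_act).to_numpy(),
            predictions[("training", combo)].to_numpy(),
        )
        # testing: K-model ensemble average over all samples
        ens = model.predict(geno, pheno, weights[combo])
        predictions[("testing", combo)] = ens
        metrics["testing"][combo] = evalmetrics.evaluate(
            actual.to_numpy(), ens.to_numpy()
        )

    if val_geno is not None:
        metrics["validation"] = {}
        val_actual = val_pheno["height_cm"].to_numpy(dtype=float)
        for combo in config.combinations:
            ens = model.predict(val_geno, val_pheno, weights[combo])
            predictions[("validation", combo)] = ens
            metrics["validation"][combo] = evalmetrics.evaluate(
                val_actual, ens.to_numpy()
            )

    report = PredictionReport(
        config=config,
        folds=folds,
        candidate_ids=candidates,
        panel=snp_panel,
        weights=weights,
        predictions=predictions,
        metrics=metrics,
        manifest=manifest,
    )
    if config.output_dir:
        write_artifacts(report, Path(config.output_dir))
    return report


def run_pipeline(config: PipelineConfig) -> PredictionReport:
    """File-based entry point: read inputs per config, run, write artifacts."""
    config.validate()
    if not config.genotype_path or not config.phenotype_path:
        raise ConfigError("genotype_path and phenotype_path are required")
    geno = plinkio.read_genotypes(config.genotype_path, config.genotype_dialect)
    pheno = plinkio.read_phenotypes(config.phenotype_path)
    val_geno = val_pheno = None
    if config.validation_genotype_path:
        val_geno = plinkio.read_genotypes(
            config.validation_genotype_path, config.genotype_dialect
        )
        val_pheno = plinkio.read_phenotypes(config.validation_phenotype_path)
    return run_pipeline_data(geno, pheno, config, val_geno, val_pheno)


_COVAR_TYPE = {"birth_year": "YEAR", "age": "AGE"}
_TYPE_COVAR = {v: k for k, v in _COVAR_TYPE.items()}


def write_weightsets(
    weights: dict[str, list[model.WeightSet]], path: Path
) -> None:
    """Serialize fitted weights to a TSV.

    SNP rows carry the training-fold mean dosage used for imputation, so
    predictions are exactly reproducible from the file.
    """
    rows = []
    for combo, ws_list in weights.items():
        for ws in ws_list:
            rows.append((combo, ws.fold, "INTERCEPT", "INTERCEPT",
                         ws.intercept, np.nan))
            rows.extend(
                (combo, ws.fold, "SNP", s, w, m)
                for s, w, m in zip(ws.snp_ids, ws.snp_weights, ws.snp_means)
            )
            rows.extend(
                (combo, ws.fold, _COVAR_TYPE[c], c, w, np.nan)
                for c, w in ws.covar_weights.items()
            )
            if ws.pc_weights is not None:
                rows.extend(
                    (combo, ws.fold, "PC", f"PC{i + 1}", w, np.nan)
                    for i, w in enumerate(ws.pc_weights)
                )
    pd.DataFrame(
        rows,
        columns=["combination", "fold", "feature_type", "feature_id",
                 "weight", "snp_mean"],
    ).to_csv(path, sep="\t", index=False)


def read_weightsets(path: Path) -> dict[str, list[model.WeightSet]]:
    """Inverse of :func:`write_weightsets` (PC-adjusted files excluded:
    the projection basis is not serialized)."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    if (df["feature_type"] == "PC").any():
        raise ConfigError("PC-adjusted weight files cannot be reloaded")
    out: dict[str, list[model.WeightSet]] = {}
    for (combo, fold), grp in df.groupby(["combination", "fold"], sort=True):
        snp = grp[grp["feature_type"] == "SNP"]
        covars = grp[grp["feature_type"].isin(_TYPE_COVAR)]
        ws = model.WeightSet(
            combination=combo,
            fold=int(fold),
            intercept=float(
                grp.loc[grp["feature_type"] == "INTERCEPT", "weight"].iloc[0]
            ),
            snp_ids=snp["feature_id"].tolist(),
            snp_weights=snp["weight"].to_numpy(),
            snp_means=snp["snp_mean"].to_numpy(),
            covar_weights={
                _TYPE_COVAR[t]: float(w)
                for t, w in zip(covars["feature_type"], covars["weight"])
            },
        )
        out.setdefault(combo, []).append(ws)
    return out


def write_artifacts(report: PredictionReport, outdir: Path) -> None:
    """Write manifest, panel, weights, predictions and metrics tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    (outdir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True) + "\n"
    )

    membership = pd.DataFrame({"snp_id": report.candidate_ids})
    for f, sel in enumerate(report.panel.per_fold_sets, start=1):
        membership[f"fold{f}"] = membership["snp_id"].isin(sel).astype(int)
    membership["final"] = membership["snp_id"].isin(set(report.panel.final_ids)).astype(int)
    membership.to_csv(outdir / "panel.tsv", sep="\t", index=False)

    write_weightsets(report.weights, outdir / "weights.tsv")

    pred_frames = []
    for (cohort, combo), series in report.predictions.items():
        df = series.rename("predicted_cm").reset_index()
        df.insert(0, "cohort", cohort)
        df.insert(1, "combination", combo)
        pred_frames.append(df)
    pd.concat(pred_frames).to_csv(outdir / "predictions.tsv", sep="\t", index=False)

    metrics_obj = {
        cohort: {combo: rep.to_dict() for combo, rep in by_combo.items()}
        for cohort, by_combo in report.metrics.items()
    }
    (outdir / "metrics.json").write_text(
        json.dumps(metrics_obj, indent=2, sort_keys=True) + "\n"
    )
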