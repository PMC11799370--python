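# cohortpgs

Cross-validated polygenic prediction of adult height that combines a SNP
panel with two non-genetic covariates — birth year (a surrogate for
secular improvements in nutrition) and age at measurement (height declines
with age) — the design used for large Han Chinese biobank cohorts, where
mean adult height rose by roughly 0.2 cm per birth year across the
1946–1986 birth cohorts.

The package is aimed at statistical geneticists who want to study this
predictor-construction recipe end to end without access-controlled cohort
data: a seeded synthetic-cohort generator reproduces the statistical
structure the analysis assumes (additive polygenic architecture with
sex-specific panels, the secular trend, age-related decline, genotype
missingness, Hardy–Weinberg-violating SNPs, close-kin pairs), and every
pipeline stage is a tested, reusable library function.

## The procedure

Males and females are analyzed separately. For one sex stratum:

1. **Quality control.** Samples are excluded for missing-call rate > 0.1,
   birth year outside [1946, 1986], a sex-mismatch flag, or 3rd-degree or
   closer kinship (KING-robust heterozygote-concordance estimator). SNPs
   are excluded for call rate < 0.9, MAF < 0.01, or Hardy–Weinberg exact
   p < 1e-8. When a validation cohort is present, analysis is restricted
   to the SNPs passing QC in both cohorts.
2. **10-fold construction.** Samples are randomly partitioned into folds
   G1..G10; each fold's training set is the other nine folds.
3. **Fold-wise GWAS.** Height is regressed on each SNP separately
   (`height ~ dosage`, OLS, complete cases) on each training set.
4. **p-value intersection.** Only SNPs with p ≤ 0.05 in *all ten*
   training-set scans remain candidates.
5. **LASSO via least-angle regression.** Each training set traces the
   L1-regularized path over the candidates and walks it while the
   training R² still improves by more than a tolerance (default 1e-4).
6. **Panel intersection.** The final panel is the intersection of the ten
   selected sets.
7. **Weight fitting.** For each covariate combination — PGS, PGS+YEAR,
   PGS+AGE, PGS+YEAR+AGE — one joint OLS fit per fold regresses height on
   all panel SNP dosages plus the covariates (optionally plus PC1–PC20 of
   the standardized genotype matrix).
8. **Ensemble prediction and evaluation.** Predictions average the ten
   fold models. Reports give the Pearson correlation r with its spread
   `sqrt((1 − r²)/(N − 2))`, the fraction of samples whose relative
   error `|ŷ − y|/y` exceeds 5%, and descriptive height statistics.

## Worked example

```python
import cohortpgs as cp

cfg = cp.CohortConfig.for_sex("male", n_samples=2000, n_snps=600,
                              n_causal=30, seed=7)
geno, pheno, truth = cp.simulate_cohort(cfg)
report = cp.run_pipeline_data(geno, pheno, cp.PipelineConfig(seed=7))

print(f"realized h2        : {truth.realized_h2:.4f}")
print(f"candidates / panel : {len(report.candidate_ids)} / "
      f"{len(report.panel.final_ids)}")
fit = cp.trendline(pheno)
print(f"trendline slope    : {fit.slope:.4f} cm/yr")
for combo in ("PGS", "PGS+YEAR+AGE"):
    m = report.metrics["testing"][combo].rounded()
    print(f"testing {combo:12s}: pcc={m['pcc']:.4f} (sd {m['pcc_sd']:.4f}), "
          f">5% discrepancy {m['discrepancy_percent']:.2f}%")
```

prints

```
realized h2        : 0.4429
candidates / panel : 21 / 21
trendline slope    : 0.2410 cm/yr
testing PGS         : pcc=0.6781 (sd 0.0165), >5% discrepancy 6.22%
testing PGS+YEAR+AGE: pcc=0.8045 (sd 0.0133), >5% discrepancy 2.26%
```

The generator hit its heritability target (0.45 ± 0.02); the fitted
secular trendline slope (0.2410) is within sampling error of the
configured 0.2258 cm/yr; and adding birth year and age to the polygenic
score raises the testing-set correlation (0.68 → 0.80) while cutting the
fraction of predictions off by more than 5% — the qualitative behaviour
the combined genetic + non-genetic predictor is designed to show.

A command-line interface mirrors the stages
(`cohortpgs simulate|qc|folds|gwas|filter|lasso|panel|fit|predict|evaluate|run-all`);
`cohortpgs run-all --geno PREFIX --pheno FILE --seed 1 --out-dir out/`
writes panel, weights, predictions, metrics and a manifest recording the
configuration hash and seed.

## Layout

| module | contents |
| --- | --- |
| `cohortpgs.synthcohort` | seeded cohort generator and ground-truth records |
| `cohortpgs.qc` | sample/SNP filters, HWE exact test, KING-robust kinship |
| `cohortpgs.assoc` | single-SNP OLS scan (vectorized, fold-batched) |
| `cohortpgs.panel` | folds, p-intersection, LARS-LASSO path, selection |
| `cohortpgs.model` | joint weight fits, ensemble prediction, PCA, VIF |
| `cohortpgs.evalmetrics` | PCC ± SD, discrepancy fraction, trendlines |
| `cohortpgs.plinkio` / `cohortpgs.pipeline` / `cohortpgs.cli` | file formats, orchestration, CLI |

`docs/methods.md` documents the generative model, parameter defaults,
numerical choices, and the known limitations of what the synthetic
cohorts can and cannot show.
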