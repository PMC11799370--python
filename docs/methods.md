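# Methods

## The generative model

Each synthetic cohort is one sex stratum. For sample *i* with birth year
`B_i`, measurement year `M_i` (independent discrete-uniform draws) and
age `A_i = M_i − B_i`:

```
height_i = μ + b·(B_i − mean B) + a·(M_i − mean M)
           + Σ_j β_j (g_ij − 2 p_j) + ε_i,       ε_i ~ N(0, σ_e²)
```

* `μ` — baseline mean height (cm); defaults 169.47 (male), 157.43
  (female), the cohort means the generator is calibrated to.
* `b` — secular trend (cm per birth year); defaults 0.2258 (male), 0.1890
  (female). The age term is written on measurement year deliberately:
  because `A = M − B`, the form `b·B + a·A` would make the *observable*
  mean-height-on-birth-year trendline slope equal `b − a`, not `b`. With
  `b·B + a·M` the two year variables are independent, so `b` **is** the
  marginal trendline slope — the quantity a cohort report actually
  prints — while `a` is still exactly the height change per year of age
  *within* a birth cohort. Fitting the full covariate model
  `height ~ year + age` on such data recovers `b + a` on YEAR and `a` on
  AGE, the usual decomposition under collinearity.
* `a` — age slope; default −0.05 cm per year of age, a mild adult height
  decline consistent with reported losses of an inch or two over decades.
* `β_j` — causal effects, drawn N(0, 1) over `n_causal` SNPs and rescaled
  as a block so the genetic share of total height variance matches
  `heritability_target` (default 0.45, between typical male/female SNP
  heritabilities of ~0.48/0.43; the realized share is recorded in the
  `TruthRecord` and lands within ±0.02 of target). Genotype centering
  uses `2p̂_j` so `μ` is the population mean regardless of frequencies.
* `σ_e` — solved by `CohortConfig.for_sex` so the *total* height SD
  matches the cohort target (6.29 male / 5.66 female) given the
  heritability and the trend variances.

Genotypes: allele frequency `p_j ~ U(0.05, 0.5)`, dosage
`Binomial(2, p_j)` (Hardy–Weinberg), independent across SNPs — the
selection pipeline never models LD, so none is simulated. Designated
violator SNPs get excess homozygosity (inbreeding coefficient F = 0.6:
exact-test p far below 1e-10 at any cohort size used here). Designated
(parent, offspring) pairs share one transmitted allele per locus
(expected kinship 1/4). Missing calls are uniform at `missing_rate`
(default 2%).

Year ranges: births 1946–1986 (the QC window), measurements 2005–2020.
The measurement window's width sets how collinear birth year and age are;
15 years gives VIF ≈ 8 for both covariates — below the conventional
threshold of 10 but genuinely collinear, matching the regime reported for
real cohorts (VIF ≈ 9). A narrower window would push VIF past 10 and make
the two covariates inseparable.

`simulate_validation_cohort` draws an independent cohort with fresh
genotypes, years and noise but the *same* causal SNPs and effect sizes —
the synthetic analogue of a second cohort sampled from one population and
genotyped on the same array. Without shared architecture, trained SNP
weights could not transfer and external validation would be meaningless.

## What the generator does not emulate

No linkage disequilibrium, no population structure (unless the
two-subpopulation test helper is used), no X chromosome, no genotyping
batch effects, no EMR-style measurement error, and effect sizes
independent of allele frequency. Passing tests therefore demonstrate that
the pipeline's statistics behave as designed under its own assumptions —
not that the predictor would reach any particular accuracy on real data,
where LD between tag SNPs and causal variants, stratification and
cohort-specific measurement practices all matter.

## Quality control

Filters use strict inequalities, so boundary values (birth year 1946,
call rate 0.90, MAF 0.01, HWE p = 1e-8) are retained. Order: sample
missing-rate/birth-year/sex-flag QC → SNP QC (MAF and HWE on observed
genotypes of the retained samples) → kinship. The HWE test is the plain
(not mid-p) two-sided conditional exact test, summing the probabilities
of all heterozygote counts no more probable than the observed one,
evaluated in log space.

Kinship uses the KING-robust between-family estimator

```
φ̂ = (N_het,het − 2 N_opp) / (2 m) + 1/2 − (h_i + h_j) / (4 m),
m = min(h_i, h_j)
```

(duplicates → 0.5, parent–offspring → 0.25, unrelated → ≈0 with a small
negative bias from the min denominator). The 3rd-degree boundary 0.0442
presumes estimates from hundreds of thousands of markers; on a
2,000-SNP simulated panel the null SD of φ̂ is ≈ 0.02, and a hard cutoff
would flag ~0.5% of all unrelated pairs — ruinous at n² /2 pairs. The
filter therefore raises the effective cutoff to
`max(0.0442, median + z·MAD)` with a Bonferroni-sized normal quantile z
over the number of pairs (`noise_guard=True`, the default; set False for
the plain cutoff). True close relatives sit an order of magnitude above
the floor at every panel size this package runs at; 2nd/3rd-degree
relatives are *not* reliably detectable on small panels — a stated
limitation, not a target.

From each flagged pair the member with the higher missing rate is
dropped; ties go to the lexicographically larger id (deterministic).

## Selection and stopping

Candidates are the SNPs with p ≤ 0.05 in all K training-set scans
(p = 0.05 exactly passes; NaN fails). Candidate columns are ordered by
genomic position before the path, which also fixes tie-breaking. The
L1 path is traced by least-angle regression with the LASSO modification
(scikit-learn's `lars_path`); predictors are standardized with
training-fold statistics and mean-imputed first. The walk stops at the
first breakpoint whose R² gain over the previous breakpoint falls below
`r2_tolerance` (default 1e-4).

Two properties of this rule are worth knowing. First, a noise
predictor's R² contribution is ~χ²/n, so the default tolerance only
screens noise for training sets of roughly 10⁴ samples and up; for
smaller cohorts the tolerance should be scaled like 1/n. Second,
consecutive LARS breakpoints can be arbitrarily close when two candidates
reach equal correlation at nearly the same penalty, so a single small
inter-breakpoint gain can stop the walk early in one fold — and since
the final panel is the intersection across folds, one conservative fold
bounds the panel. Selected-set sizes therefore vary between seeds; the
evaluation metrics remain internally consistent (the PGS-only testing
correlation tracks the square root of the heritability actually captured
by the final panel, whatever its size). `r2_tolerance` and `max_steps`
are exposed in `PipelineConfig` for users who want a different
trade-off.

## Weights, prediction, evaluation

Each covariate combination is **one joint OLS fit** of height on all
panel dosages plus covariates (not a two-stage score-then-covariate
regression), per fold, with rank-deficient columns dropped and refit.
Missing dosages are imputed with the training fold's SNP means, stored in
the `WeightSet`, and reused verbatim at prediction time — target-cohort
statistics never enter a prediction.

Ensemble semantics mirror the cross-validation design: *testing* metrics
average all K fold models over every sample (each sample sits in K−1 of
those models' training sets, so this figure is optimistic — which is why
an external validation cohort is the meaningful benchmark); *training*
metrics pool each fold model's in-sample predictions (reported n is
therefore K·(K−1)/K·n); *validation* applies the same K-model average
with frozen weights.

PCA adjustment, when enabled, fits one basis per sex on the standardized
QC-passed training genotypes (matching how the eigenvalue table of a real
cohort is produced once, not per fold) and appends the top 20 projections
to every design matrix. The Kaiser count (eigenvalues > 1) is reported
but does not change the fixed `n_pcs = 20`. On structure-free synthetic
data all eigenvalues sit near 1 and the adjustment moves testing
correlations by well under 0.02.

Metrics: Pearson r with the spread `sqrt((1 − r²)/(N − 2))` — formally
the large-sample standard error of r, reported under the conventional
label `pcc_sd`; the strict fraction of samples with
`|ŷ − y|/y > 0.05`; and mean/SD/median/range summaries. Printed values
round half-to-even to the customary precisions (r to 4 decimals, percent
and heights to 2); machine output keeps full precision. Trendlines
regress *per-birth-year mean* height on birth year (one point per year,
the way cohort trend figures are drawn); a per-individual mode exists
behind a flag.

## Problem sizes and determinism

The shipped study conditions are 5,000 samples × 2,000 SNPs with 50
causal SNPs per sex; the replicated parameter-recovery suite runs 20
seeds at exactly these conditions, and `scripts/acceptance.py` adds a
2,500-sample shared-architecture validation cohort per sex. All
randomness flows through explicit integer seeds into
`numpy.random.default_rng`; identical seed + config reproduce genotypes,
phenotypes, fold assignments and every downstream artifact bit for bit
(the pipeline manifest records a hash of the scientific configuration).

## Known limitations

* Panel sizes are sensitive to the stopping rule (above) and to fold
  luck; the package reports per-fold selection sizes in the manifest so
  this is visible.
* The kinship stage cannot resolve 3rd-degree relatives on small
  simulated panels (estimator noise), only 1st degree and duplicates.
* PC-adjusted weight files cannot be reloaded from TSV (the projection
  basis is not serialized); use the in-memory pipeline for PCA runs.
* The GWAS stage fits no covariates by design (the procedure's step is
  `height ~ SNP` alone); confounding control happens only through the
  final joint fit.
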