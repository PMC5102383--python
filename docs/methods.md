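# Methods

This note documents the models and procedures `skinyouth` implements,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical/design choices that were genuinely open.

## Phenotype model

The quantitative phenotype is built in three steps. The skin age score
(SAS) is the **median** of the per-subject clinician ratings — medians
because ratings are ordinal whole-year judgments and a single outlying
rater should not move the score. `delta = CA − SAS` measures how much
younger (positive) or older (negative) the skin looks than the calendar
age. Because the spread of delta grows with age, delta is regressed on
CA by OLS **over all subjects** (not only the elderly stratum — the
regression's purpose is to remove the cohort-wide age trend), and the
residual `r_delta` is the age-corrected youthfulness measure.

Classification: subjects with CA < 30 are "young" (positive controls),
30 ≤ CA < 50 "mid-age". Within the eligible stratum (CA ≥ 50,
inclusive — the eligibility wording is ambiguous between "over 50" and
"50 and older"; we take inclusive ≥ 50), the `ceil(0.10·m)` subjects
with the highest r_delta are SY, ties at the boundary broken by subject
id for determinism, and subjects at or below the stratum's 50th
percentile of r_delta are non-SY. Whether the "lower 50%" cut should be
taken within the eligible stratum or over the whole cohort is also
ambiguous; the stratum is the default and
`classify_subjects(nonsy_within_stratum=False)` gives the other
reading. SY membership always wins over non-SY in the degenerate case
where the two rules would overlap.

## Preprocessing

1. **Depth normalization** scales every sample to 10⁷ mapped reads
   (3'-seq counts one unit per transcript, so no length correction).
2. **Expression filter**: keep genes with mean normalized value
   strictly > 2, applied on the count scale before the log transform
   (the filter's natural scale).
3. **log₂(x + 1)**: pseudocount 1 so zeros map to zero and count-scale
   values stay interpretable.
4. **Batch adjustment** implements the parametric empirical-Bayes
   location/scale model: per gene, standardize by the batch-design
   grand mean and pooled variance; per batch and gene estimate a
   location γ̂ and scale δ̂²; shrink γ̂ toward a per-batch normal prior
   and δ̂² toward a per-batch inverse-gamma prior (hyperparameters by
   method of moments), solving the coupled shrinkage equations by
   fixed-point iteration (tolerance 1e-4 on the relative change, cap
   500 iterations, non-convergence is an error reporting the residual);
   remove the shrunken effects and restore the gene's scale. We verified
   agreement with the reference R implementation (`sva::ComBat`) to
   ~1e-7 on fixtures. One deliberate difference: after adjustment each
   gene is recentered to its original grand mean. EB shrinkage otherwise
   leaves a small per-gene offset; pinning the grand mean makes the
   operation exactly location-preserving, and since the offset is
   constant within a gene it is invisible to every downstream contrast.
   A single batch is a no-op by contract. No biological covariates enter
   the standardization model: adjustment happens before any phenotype
   modeling.

   The EB shrinkage leaves residual batch-mean differences proportional
   to the sampling noise of the per-gene batch means; removal is
   near-exact only when within-batch noise is modest relative to the
   shift. Fixture sizes in the tests (300 genes, 20 samples/batch,
   within-batch sd 0.1 against a +3 shift) were chosen so the residual
   gap is comfortably below 0.05 log₂ units.

## Differential expression

Per gene, OLS with intercept on one covariate. The residual-variance
prior (d₀, s₀²) is estimated by moment matching on
`e_g = log s²_g − ψ(d/2) + log(d/2)`: the mean of e identifies log s₀²
and its excess variance over ψ′(d/2) identifies d₀ through the inverse
trigamma (Newton iteration). When the observed log-variances are no
more dispersed than sampling alone explains, d₀ = ∞ and the prior
variance is the plain mean of the s²_g (complete pooling; this matches
the reference implementation and the identical-variances limit, where
the log-scale bias correction would otherwise misplace s₀²). Moderated
t uses the posterior variance and d₀ + d degrees of freedom (normal
when d₀ = ∞). Genes with exactly zero residual variance are reported
untestable (NaN p) and excluded from prior estimation rather than
producing p = 0. The whole chain agrees with `limma::eBayes` to
machine precision on fixtures.

Age genes: regression on CA, BH FDR < 0.01 (the genome-wide screen).
SY genes: expression is residualized on CA first, then the residuals
are regressed on the binary SY indicator; genes are called at raw
p < 0.01 — the small-contrast convention, with the BH column still
reported. The age residualization is fit on the compared (SY ∪ non-SY)
samples by default; `residualize_on="all"` fits it on every sample
first, for the reading where the age trend is learned cohort-wide. Both
contrasts are two-sided. After residualizing on age, the indicator
model's residual df is taken as n − 2; the df spent on the age fit is
ignored, which is slightly anticonservative at n = 45 (≲ 2% on the
df) and was judged negligible against the moderation's added df.

## Statistics

Welch's t (Satterthwaite df) for continuous covariate balance; Fisher's
exact test with the two-sided "sum all tables no more probable than
observed" rule and a 1e-7 relative slack against floating-point ties
(the convention of the R environment the balance tables come from);
Wilcoxon rank-sum with an exact enumerated permutation null (mid-ranks
for ties) when both groups are below 25 samples *and* the number of
group splits is at most 5·10⁵, falling back to the tie-corrected
normal approximation otherwise; Pearson correlation with the t-based
p on n − 2 df; qPCR ΔCt with technical replicates averaged before
subtraction. The balance report is null-true by construction on
synthetic cohorts because covariates are simulated independently of the
latent youthfulness.

## Gene-set analysis

The original set-level analysis was run in a GUI tool whose internal
algorithm is not publicly specified; this package implements a
documented stand-in with the same user-facing parameters: changed-gene
calling at a minimum expression change of 0.3 log₂ units on the
residualized group means (boundary inclusive, for determinism), a
one-sided hypergeometric over-representation test per set and
direction (up/down tested separately, both reported), and BH control at
0.1 across all set × direction tests. Sets with no members in the
universe are skipped with a warning. The cumulative set-level
comparison computes per-gene group means over set members and tests the
paired differences with the Wilcoxon signed-rank (a KS two-sample
alternative is exposed via `method="ks"`); the location test presumes a
coherent shift direction within the set.

## Synthetic data

The generator emulates the study's structure: n = 122 women aged 18–89
(whole years, uniform), four clinician raters, ~5000 genes, two
sequencing batches, negative-binomial counts with a log-normal
library-size factor (per-sample totals land near real 3'-seq depth of
14–44M reads at the default gene count and baseline range of 2–14
log₂ units).

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| `rater_sd` | 4 yr | inter-rater spread is unreported; 4 yr gives realistic disagreement between whole-year ratings |
| `delta_slope` | 0.1 yr/yr | mild growth of mean delta with age |
| `delta_noise_base`, `delta_noise_age` | 1 yr, 0.08 yr/yr | latent spread of delta ≈ 2–8 yr over the age range, widening with age |
| `n_age_genes`, `n_sy_genes` | 100, 50 | scaled-down counts of responsive genes |
| `age_effect_log2_per_year` | 0.02 | ≈ 1.4 log₂ units across the age span |
| `sy_effect_log2` | 2 | a strong, clearly recoverable group effect |
| `nb_dispersion` | 0.1 | typical bulk RNA-seq overdispersion |
| `batch_shift_log2` | 0.5 | sd of gene-specific batch shifts |

Design choices inside the generator:

- The latent youthfulness u ~ N(0,1) enters the true skin-age score
  scaled by the age-dependent noise sd, so delta = slope·age +
  u·(base + coef·age): the spread widens with age and the residual
  phenotype can recover the top-u·sd subjects.
- **Ground truth for SY** is the residual of the *noise-free* delta on
  age (what the scoring computes at zero rater noise). Ranking truth by
  raw u instead is not recoverable even in principle: the age-dependent
  scale and the fitted line's tilt reorder subjects near the decile
  boundary.
- **Batch shifts are gene-specific**, drawn N(0, `batch_shift_log2`)
  per gene with the first batch as reference. A shift common to all
  genes would be indistinguishable from library size and removed
  exactly by depth normalization — it would make the batch-adjustment
  stage untestable, and real batch effects are gene-specific anyway.
- **Effect genes are drawn from below the top abundance quintile.** In
  the real data, differential transcripts are a negligible share of
  library mass; at scaled-down gene counts, random planting can put
  4-fold effects on genes carrying >15% of the library, and total-count
  normalization then shifts *every* null gene between groups — a
  compositional regime the method is never used in. Restricting planted
  effects to sub-top-quintile abundance restores realistic mass shares.
- Covariates (BMI, smoking, skin cancer history, UV score) are drawn
  independently of u, so the covariate-balance analysis is null-true by
  construction.
- `nb_dispersion = 0` degenerates to deterministic rounded means, which
  gives exact identities for testing.

What the generator does **not** emulate: gene–gene correlation,
mean-dependent dispersion, zero inflation, GC/length bias, rater
systematic offsets, and any real biological pathway structure. Passing
recovery tests therefore demonstrates the pipeline's statistical
machinery under its own assumptions, not performance on real 3'-seq
data — in particular the moderated test's calibration on real data
also depends on the mean–variance trend that this generator only
partially reproduces.

## Problem sizes and tolerances in the tests

Simulation-based checks run at 500–5000 genes and 45–122 samples —
large enough for stable recovery statistics, small enough for a
single-CPU suite. The null-calibration check averages the flagged
fraction over five independent label draws on one null matrix (a lower-
variance estimate of the same rate; a single draw is super-binomially
variable because the shared variance prior moves all genes together)
and compares against 1% with a 99.9% binomial band. Monotone recovery
criteria (≥ 80% / ≥ 90%) follow the corresponding planted-effect
designs directly. Floating-point equality is asserted at the scale of
the computation: machine-precision against closed forms, 1e-5 against
the R reference runs.

## Known limitations

- No voom-style precision weights; at very low counts the moderated t
  on log₂ values is mildly miscalibrated (conservative), as on any
  real 3'-seq data analyzed this way.
- The enrichment stand-in is an over-representation test, not a
  running-sum (GSEA-style) statistic; results on graded signals will
  differ from weighted-KS tools.
- `fisher_exact` and the exact Wilcoxon path are exhaustive and meant
  for the small tables / groups of the covariate analyses, not for
  large-sample screening.
- The pipeline assumes one count matrix per cohort; meta-analysis
  across cohorts is out of scope.
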