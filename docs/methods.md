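# Methods

This note documents the statistical models, the synthetic-cohort
generator, the numerical choices, and the known limits of what the test
suite demonstrates.

## Preprocessing chain

The chain runs in a fixed, logged order: contaminant/prevalence filter →
internal-standard (IS) assignment → IS normalization → QC-median batch
centering → half-minimum imputation → CV filter → log z-scores. Every
input feature receives exactly one fate (`retained`, `dropped_blank`,
`dropped_prevalence`, `dropped_r2`, `dropped_cv`, `dropped_all_below_lod`,
`dropped_zero_variance`), recorded in the QC report.

Choices where convention had to be fixed:

- **Contaminant rule.** Blank comparison is implemented as a blank-ratio
  heuristic: a feature is dropped when its mean blank signal (absent
  cells as zero) exceeds 50% of its mean study signal. The threshold is
  configurable (`blank_ratio_max`). With no blank injections the step is
  skipped with a warning.
- **Prevalence.** Detection prevalence is computed over all non-blank
  injections (study + QC); the floor is 5%.
- **IS correlation on the log scale.** R² is the squared Pearson
  correlation between log feature and log IS abundance across QC
  injections, pairwise-complete, reflecting a multiplicative error model.
  A zero-variance IS scores R² = 0; argmax ties break by IS column order.
  Features whose best R² is below 0.75 are omitted.
- **Normalization** is the per-injection ratio (abundance / chosen IS),
  not a regression residual. An IS value that is missing or non-positive
  makes the cell below-LOD rather than raising.
- **Batch centering.** Correction factors are multiplicative on the
  normalized scale: global QC median over batch QC median, per feature.
  After correction every batch's QC median equals the global QC median to
  floating tolerance, and re-running the step yields factors of 1. A
  batch with no usable QC value for a feature gets factor 1 with a
  warning. Because the global reference is arbitrary, parameter-recovery
  comparisons against simulated truth are made after centering the log
  factors within feature.
- **Half-minimum imputation** runs after batch correction and before the
  CV filter and log transform; the below-LOD marker is NaN throughout
  (never zero), so the rule is unambiguous.
- **CV filter.** CV(%) = 100·SD/mean over QC injections on the
  post-correction, pre-log scale (CV is scale-free and conventionally
  reported on raw abundances); ceiling 30%. The report carries the median
  and IQR of CVs across retained features.
- **z-scores** use the sample SD (ddof = 1) of log abundance over study
  samples only; zero-variance features cannot be standardized and are
  dropped.

## Association models

The outcome screen fits one linear model per metabolite with a shared
adjustment set (infant sex; maternal age, parity, education, ethnicity,
pre-pregnancy BMI, weight gain to 26–28 wk, height, tobacco-exposure
category, physical activity, diet-quality score, GDM). Categoricals are
dummy-coded against their first configured level; a dummy level absent
from the analysis rows is dropped with a warning; a genuinely collinear
block (condition number > 1e8 after standardization) raises. The
per-metabolite coefficient, SE and t-based CI are computed by exact
Frisch–Waugh–Lovell residualization — one QR factorization of the
covariate block serves all metabolites, and the result is identical to
per-metabolite OLS (asserted against statsmodels in the tests). Gestational
age is not an adjustment covariate in the birth-size models; the
birth-weight-for-GA z-score used by one sensitivity scenario is an
internal standardization (residual of birth weight on GA within infant
sex, scaled to unit SD), a deliberate substitute for an external growth
reference.

GDM is derived from glucose (fasting ≥ 7.0 or 2-h ≥ 7.8 mmol/L, WHO
cutoffs, boundaries inclusive); one high observed value suffices for a
positive flag, while a negative classification requires both values
observed. Pre-pregnancy overweight is BMI ≥ 23 kg/m² (Asian cutoff,
boundary inclusive), underweight < 18.5; preterm is GA < 37 completed
weeks.

Multiplicity is controlled per outcome family (one BH family per outcome
block; configurable to a pooled family). Tier boundaries: q < 0.05
significant; q = 0.05 classified as trend; q = 0.10 as null.

**Profiling direction.** Metabolite z-scores are regressed on the full set
of maternal characteristics (BMI entering as the overweight/underweight
flags). The three ethnicity contrasts come from separate one-vs-rest
refits, each replacing the 3-level factor with a single indicator;
non-ethnic estimates come from the base model with the full factor.
q-values are BH within characteristic across metabolites.

**Interaction.** Effect modification by ethnicity is tested per metabolite
with the two products of the metabolite z-score and the non-reference
ethnicity dummies, jointly, using the OLS F statistic (2 df; the
finite-sample Wald test — the test family was an open choice). Metabolites
with interaction q < 0.05 are refitted within each ethnic stratum with
ethnicity removed from the covariates; strata below 30 subjects
(configurable) are skipped.

## Multiple imputation

Missing covariates are filled by chained equations: a Bayesian linear
draw for continuous variables and multinomial-logistic category draws
(ridge-regularized Newton fit) for binary and multi-level variables, with
the outcomes and all analysis covariates as predictors (congenial with the
analysis models). Parameter uncertainty is propagated by fitting each
sweep's model on a bootstrap resample of the observed rows — the "boot"
flavour of chained equations — and predictive noise is always drawn, so
imputations are posterior-predictive rather than conditional means.
Defaults: m = 20 imputations, 10 burn-in sweeps, independent chains with
seeds spawned from the run seed. Pooling follows Rubin's rules
(Q̄, W, B, T = W + (1+1/m)B) with ν = (m−1)(1 + W/((1+1/m)B))² degrees of
freedom and the normal limit when B = 0. With zero missing cells the m
tables equal the input and the pooled screen reproduces the complete-case
screen exactly.

## Synthetic-cohort generator

The generator is first-class, tested code; its defaults are the study
conditions everything else is evaluated under.

- **Covariates.** Ethnicity 55/26/19% Chinese/Malay/Indian; age
  30.5 ± 5.1 y; pre-pregnancy BMI ethnicity-specific (Chinese 21.6 ± 3.4,
  Malay 24.2 ± 5.4, Indian 23.9 ± 4.5 kg/m², giving ≈43% overweight at
  the ≥23 cutoff); glucose levels giving ≈16% GDM under the WHO cutoffs;
  the remaining marginals (education, activity, tobacco, parity, height,
  weight gain, diet score) set to plausible cohort values.
- **Metabolome.** Log-concentration = baseline + covariate effects +
  exchangeable-correlation noise: a shared subject factor with ρ = 0.2
  plus idiosyncratic noise, unit SD in total. Default covariate effects
  plant ethnicity contrasts on metabolites 1–10, BMI effects on 11–20 and
  diet effects on 21–28, grounding the profiling direction.
- **Outcomes.** Each outcome is its calibration mean (birth weight
  3094 g, length 48.6 cm, skinfold sum 10.3 mm) plus sample-centred
  covariate effects, planted per-SD metabolite effects, and Gaussian
  noise whose SD is set so the marginal SDs land near 451 g / 2.3 cm /
  2.2 mm. Gestational age is a truncated normal on [30, 42] wk with
  SD 1.4 whose location is solved numerically so P(GA < 37) = 7.6%.
  Default planted effects: 28 metabolites on the skinfold sum with
  |β| = 0.3 mm/SD and balanced signs — balance keeps the null metabolites
  marginally null under the exchangeable correlation, which makes the
  false-discovery proportion in the FDR simulation well defined; an
  effect may optionally be restricted to one ethnic group for interaction
  studies.
- **Instrument.** Injections run batch by batch: blanks first, then study
  samples with a pooled-QC injection after every 7th study sample (plus a
  trailing QC when a partial block remains, so every batch has at least
  one QC). Measured abundance = exp(latent + feature×batch offset +
  IS-group injection factor + noise); each IS channel shares the
  injection factor of its group, so each metabolite is maximally
  QC-correlated with exactly one IS (the ground-truth map is retained).
  Default SDs (log scale): injection factor 0.40, feature and IS batch
  offsets 0.10, measurement noise 0.05 — chosen so that true-IS R²
  concentrates well above the 0.75 threshold while off-group R² stays far
  below it. Per-feature censoring at the 2% abundance quantile supplies
  below-LOD cells; 4 contaminant features (blank signal ≈ 1.2× study) and
  6 rare features (present in ≈3% of injections) are appended as decoys.
  QC aliquots carry the pooled-sample mean concentration. Blanks receive
  neither plasma features nor IS spikes.
- **Missingness.** Exact per-covariate counts at the n = 940 calibration
  (height 9, diet 9, activity 10, education 11, alcohol 25, glucose 36,
  BMI 66, weight gain 73, tobacco 73); MCAR by default, MAR optionally
  weights selection by observed ethnicity/education. Outcomes are never
  masked.
- **Seeding.** One global seed spawns independent child streams per stage
  (covariates, metabolome, outcomes, instrument, missingness) via
  `numpy.random.SeedSequence.spawn`, so each stage is reproducible alone
  and full runs are byte-identical under a fixed seed.

What the generator does *not* emulate: chromatographic drift within
batch, retention-time misalignment, heteroskedastic intensity-dependent
noise, non-linear covariate–outcome relations, and MNAR covariate
missingness. Passing tests therefore demonstrate correctness of the
pipeline's algebra and its behaviour under the stated error model, not
robustness to those real-data pathologies.

## Problem sizes used in the checks

Simulation-based checks run at sizes chosen to keep Monte-Carlo error
well inside the asserted tolerances: calibration means over 12–20 cohorts
of n = 940; FDR control over 200 cohorts of n = 940 × 134 metabolites
(fast because the screen is a single QR plus vectorized slopes);
CI-coverage over 200 replicates of n = 250 with independent metabolites
(ρ = 0, so the planted β is the estimand — under exchangeable correlation
the marginal slope attenuates to (1−ρ)β and coverage of the generative
value would be the wrong check); MI coverage over 120 replicates with
m = 5 chains; preprocessing recovery on a 400-subject, 40-metabolite,
5-batch study.

## Numerical conventions

- Quintiles are rank-based with ties assigned to the lower quintile.
- The trend test regresses a characteristic on the subject's
  quintile-median outcome value; a constant characteristic returns
  p = 1 by decision.
- The Cochran–Mantel–Haenszel statistic is the generalized
  general-association form without continuity correction; with one
  stratum it equals (n−1)/n × Pearson chi-square. Empty rows/columns are
  collapsed with a warning.
- Below-LOD is an empty cell in peak-table CSVs; covariate missingness is
  the string `NA` in cohort CSVs — the two have different downstream
  semantics. Results TSVs carry 12 significant digits; row order is
  target, then q ascending, then metabolite id.
- RSS in the screen is clipped at zero before the square root (exact fits
  can produce −1e-20 by cancellation).

## Limitations

- The imputation sampler approximates parameter posteriors by the
  bootstrap; for very small strata the multinomial ridge (1e-4) shrinks
  category probabilities slightly toward uniform.
- The interaction analysis is complete-case; pooling interaction F tests
  across imputations would need a multivariate combining rule that is out
  of scope.
- The profiling direction treats each imputed table's fit as exchangeable
  and pools per-term estimates by Rubin's rules; categorical
  characteristics contribute one row per non-reference level rather than
  a joint test.
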