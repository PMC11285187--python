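# Methods

This note records the statistical models `gmnet` implements, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that matter for reproducing results.

## Data model

All analyses operate on a long-format cohort table: one row per
subject-visit, with subject/trial/site identifiers, phenotype (RR, SP, PP),
treatment arm, visit index, time in years from baseline, baseline age, sex,
disease duration, total intracranial volume (TIV, mm³), EDSS (0–10 in half
points, missing allowed) and R regional GM volumes (mm³). Validation is
strict and happens at construction: unique (subject, visit) keys, a
baseline (t = 0) row per subject, strictly increasing visit times,
non-negative volumes, subject-constant covariates. Whole-brain GM is
defined as the sum of the regional volumes — the only definition
reconstructible from region-level data. Missing EDSS rows are dropped only
in EDSS models (complete case per analysis), never imputed. Region count is
configurable; a 125-region atlas-based parcellation is typical, and the
test suite uses 40–60 regions for speed.

## Spatial ICA

ICA is fit on the observation × region matrix with observations as
samples: the independent sources are then the per-observation network
loadings and the mixing rows are the spatial maps — the convention that
directly yields a network measure per participant per time point. (The
alternative, regions as samples, yields group-level maps only; the chosen
convention is recorded in the serialized model.) We use scikit-learn's
FastICA: logcosh contrast (a = 1), symmetric (parallel) fixed-point
updates, PCA whitening to K components, tol 1e-4, default max_iter 200
(the CLI uses 500). K defaults to 20 — deliberately generous so weaker but
interesting patterns are not truncated — and is set to the planted K in
validation runs. Raw volumes enter ICA; TIV is a covariate in the
statistical models only.

Numerical notes: the stored whitening matrix is scaled so whitened data
have exactly identity covariance (1/n convention), with the inverse factor
absorbed into the unmixing rotation, so `loadings = (X − mean) · Wᵀ · Uᵀ`
holds verbatim for prospective projection. Regions with zero variance are
excluded from the decomposition (their map and whitening entries are
zero): besides carrying no signal, exact-zero columns can poison the SVD
sign convention in degenerate noiseless data. Non-convergence is returned
with a flag and a logged warning, not an exception.

**Sign orientation.** An ICA component's sign is arbitrary, so each
loading is correlated with whole-brain GM and both the loading and its map
are negated when the correlation is negative; the product
`loadings · maps` is unchanged and afterwards a lower loading always means
lower GM volume. Zero-variance loadings are left unoriented with a warning.

**Stability matching.** Two decompositions (e.g. on disjoint cohorts) are
compared by all-pairs Pearson correlation of spatial maps with an optimal
one-to-one assignment (Hungarian algorithm on |r|); matched pairs with
|r| ≥ 0.8 are flagged consistent. The assignment rule is ours: thresholded
spatial cross-correlation alone does not define a matching when components
correlate with several counterparts.

## Lasso surrogate

One Lasso per network maps regional volumes to the ICA loading, so unseen
participants/visits can be scored without re-estimating the ICA. The
cohort is split 70/30 **by subject** (never by row — visit-level splits
leak within-subject information), penalties are selected per network by
5-fold subject-grouped cross-validation over a log-spaced grid from λ_max
(the smallest penalty that zeroes all coefficients) down four decades, and
the model is refit on the full training split. Standardization parameters
(per-region mean/SD) are frozen from the training split and serialized;
prospective application performs no estimation of any kind. Fidelity is
summarized as ICC(2,1) — two-way random effects, absolute agreement,
single measures (Shrout–Fleiss) — between direct ICA loadings and
surrogate predictions on the held-out 30%. Absolute agreement is the
right form because the surrogate must reproduce the loading's value, not
merely rank participants consistently. On the default synthetic
conditions the minimum held-out ICC across networks exceeds 0.99; this is
expected rather than impressive, because ICA loadings are by construction
affine in the input volumes, so an L1-penalized linear model can match
them almost exactly — the validation guards against leakage and pipeline
defects, not model misspecification.

## ComBat harmonization

Site/scanner effects are removed from the network measures and whole-brain
GM (not the raw regional volumes) with parametric ComBat: per feature, a
location/scale model with batch effects shrunk by empirical Bayes — normal
prior on batch locations, inverse-gamma on squared scales, hyperparameters
estimated across features, posteriors found by the standard coupled
iteration (tolerance 1e-6, cap 500). Biological covariates (defaults: age,
sex, time) are estimated jointly and added back untouched. With a single
batch the data are returned unchanged. The implementation matches the
canonical R reference (`sva::ComBat`) to ~1e-9 on shared inputs (frozen in
the test suite).

A caution documented by the tests: parametric ComBat is only
*approximately* idempotent. EB shrinkage leaves a small residual batch
difference after one pass, which a second pass re-shrinks; on realistic
designs the second pass moves values by up to a few percent of an SD (the
R reference behaves identically). Harmonize once.

## Mixed models

All longitudinal models are linear mixed models with a subject random
intercept plus residual. With one observation per visit, a "visit nested
within subject" random structure is statistically exactly this: a
visit-level random effect would be confounded with the residual. REML
estimation is profiled down to one dimension — the variance ratio
λ = σ²_subject/σ²_resid — and minimized by a log-grid scan plus bounded
Brent refinement; β is the GLS solution at λ̂. On balanced designs this
reproduces the closed-form ANOVA variance estimators to ~1e-8, and the
boundary λ = 0 (no between-subject variance) is reached exactly. Inference
is Wald z with CIs computed literally as β ± 1.96·se; this is accurate at
the cohort sizes of interest (hundreds of subjects) and is a documented
limitation for very small n, where Satterthwaite-type corrections would be
preferable.

Analysis families, each FDR-corrected (Benjamini–Hochberg step-up) across
the K networks + whole-brain GM within one contrast within one analysis:

- **Phenotype trajectories** — measure ~ phenotype × time + age + sex +
  duration + TIV + treatment. Baseline contrasts are the phenotype main
  effects against a configurable reference (default SP); slope contrasts
  are the interactions; the analysis can be re-run with any reference
  level, and contrasts map exactly under reparameterization.
- **EDSS associations** — EDSS ~ loading_z × time + covariates, complete
  case on EDSS, loadings z-scored so coefficients are per-SD and invariant
  to measure rescaling. The loading main effect is the baseline
  association; loading × time is the progression term. The tested subset
  of networks is caller-selectable (clinically motivated subsets in real
  use).
- **Stepwise selection** — bidirectional OLS stepwise by AIC over network
  measures + whole-brain GM with forced covariates (age, sex, duration,
  treatment, TIV, number of visits) always retained; outcomes are baseline
  EDSS or the per-subject OLS slope of EDSS on time (our operationalization
  of "EDSS change"; subjects need ≥ 2 observed EDSS values). Reported fit is
  adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1).
- **Treatment effects** — measure ~ time × arm + age + sex + TIV. Effect
  sizes use each subject's first-to-last-visit change (earliest and latest
  available visit; single-visit subjects excluded with a logged count):
  Cohen's d = arm difference of mean change over the pooled change SD,
  unadjusted for covariates by default. Per-arm sample size is the
  smallest integer n for which the two-sided two-sample t-test at level α
  (noncentrality d·√(n/2), df 2n − 2) reaches the target power, by exact
  noncentral-t evaluation — matching standard power software (64 per arm
  at d = 0.5, 17 at d = 1.0 for α = 0.05, power 0.80).

**Annual percentage change** is 100 · slope / |group baseline mean|, with
a guard: when the baseline mean is negligible against the measure's SD
(as can happen for centered ICA loadings), the absolute slope is reported
with a not-a-percentage flag instead of an exploding ratio.

## Synthetic cohorts

The generator plants: K sparse non-negative spatial maps (each 3 to R/4
regions, Dirichlet weights summing to 1, pairwise support overlap < 50%);
per-region baseline means (6,000–12,000 mm³); per-subject baseline
loadings, Laplace-distributed (SD 3,000 mm³) around phenotype-specific
means — heavy tails make the sources ICA-identifiable, and the phenotype
means create baseline group differences; phenotype-specific annual drifts
(RR −30…−5, SP −60…−25, PP −55…−20 mm³/yr) with visit-level noise
(SD 150); an additive slope increase of 30–45 mm³/yr under treatment on 3
networks, sized a priori so the time × arm Wald z is ≈ 6 at the default
application-cohort size (300 subjects/arm, 4 annual visits); EDSS as an
affine function of 3 designated clinical networks plus age, rounded to
half points and clipped to [0, 10], 5% missing; multiplicative per-region
site gains in [0.98, 1.02] over 4 sites; TIV scaling (mean 1.45 × 10⁶ mm³,
SD 15,000) applied multiplicatively with all volumes expressed relative to
a reference TIV. Default cohort: 100 subjects per phenotype × arm cell
(600 total), 4 annual visits. Non-positive volumes after noise are
resampled up to a retry cap, then error.

Two generator choices are deliberately conservative relative to real data.
Head-size variation (TIV SD ≈ 1%) and site gains (± 2%) are kept small so
that the planted networks — not the global head-size direction or
between-site contrasts — occupy the top-K covariance eigenspace; with
realistic 10% TIV spread, a K-component decomposition spends one component
on global scale and the weakest planted network is lost, which is a
property of the method (and an argument for fitting K above the expected
network count, as the default K = 20 does), not a defect to hide in
validation. Harmonization is stressed separately with large planted shifts.
The generator also omits dropout/informative missingness, scanner noise
physics, and floor/ceiling structure in EDSS beyond rounding; passing
tests therefore demonstrate correctness of the machinery on data whose
generative assumptions match the models, not robustness to real-world
violations of them.

## Problem sizes and determinism

Validation runs use 8 networks over 60 regions with 600-subject cohorts
(surrogate fidelity), two disjoint 402-subject cohorts (stability),
10,000 simulated t-tests (power self-consistency), and 1,500-replicate
Monte Carlos for type-I error and CI coverage — sizes chosen so the whole
battery completes in a couple of minutes on one CPU while keeping Monte
Carlo standard errors well inside the asserted bands. Every stochastic
step takes an explicit seed; pipeline stages derive per-stage seeds from a
global seed via seed sequences, and identical configuration + seed
reproduces byte-identical artifacts.
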