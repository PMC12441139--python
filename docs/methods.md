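# Methods

This note documents the statistical models implemented in `vbmrep`, the
design decisions taken where the design was genuinely open, what the
synthetic generator does and does not emulate, and the package's numerical
conventions and limitations.

## CTQ scoring and severity categorization

The Childhood Trauma Questionnaire is scored as five subscale sums
(emotional abuse EA, physical abuse PA, sexual abuse SA, emotional neglect
EN, physical neglect PN; five items each, 1–5 per item) plus the total
(25–125). Items are assumed already recoded (reverse-keyed items flipped);
denial/minimization items of the 28-item form are ignored. The default
item→subscale map is positional (items 1–5 → EA, …, 21–25 → PN) and
configurable, since exports of the real instrument interleave subscales.

Severity bands use the conventional subscale cutoffs (severe lower bounds
EA 16, PA 13, SA 13, EN 18, PN 13; none-to-minimal upper bounds EA 8, PA 7,
SA 5, EN 9, PN 7). A participant is *severe* when any subscale reaches its
severe cutoff, *none-to-minimal* when every subscale is at or below the
lower band, otherwise *intermediate* and excluded from extreme-group
contrasts. Cutoffs are configuration, and every analysis records the
cutoffs used.

The abuse composite is EA+PA+SA and the neglect composite EN+PN — sums of
subscale sums. A joint-regressor parameterization of "the abuse subscales"
would be an alternative; the sum was chosen as the simplest scalar
operationalization consistent with one tested predictor column per model.

## The model grid

Eighteen mass-univariate models are fitted per cohort and pooled. All
covary age, sex and TIV; lifetime MDD diagnosis is additionally controlled
where indicated:

| Model | Predictor | Diagnosis covariate | Subsample |
|---|---|---|---|
| 1 | CTQ sum | yes | HC+MDD |
| 2 | CTQ sum | no | HC+MDD |
| 3 / 4 | CTQ sum | – | HC / MDD |
| 5 / 6 | abuse / neglect composite | yes | HC+MDD |
| 7–11 | EA / PA / SA / EN / PN | yes | HC+MDD |
| 12 / 13 | extreme groups (severe=1, none=0) | yes / no | HC+MDD |
| 14 / 15 | extreme groups | – | HC / MDD |
| 16 | CTQ sum | – | medication-naive MDD |
| 17 / 18 | CTQ sum × age | – | HC / MDD |

Main effects use one-sided negative tests, p = P(T_df ≤ t) (the directional
hypothesis is gray-matter *reduction* with maltreatment); interaction
models use two-sided tests. Interaction designs center CTQ sum and age
before forming the product (reduces collinearity with the always-included
main effects; the scientific hypothesis concerns the product term).
Sex-stratified reruns drop the sex covariate (rank safety); cortical
thickness endpoints drop TIV. Extreme-group predictors are coded severe=1,
none=0 so the one-sided test expects a negative coefficient.

Per voxel, ordinary least squares gives β, t = β/se, and the effect size

    partial R² = t² / (t² + df),   df = n − rank(X),

which equals the nested-model identity (RSS_reduced − RSS_full)/RSS_reduced
(verified to 1e-10 in tests). Voxels with exactly constant response are
excluded from maps with a logged count rather than propagating NaN.

The analysis mask keeps voxels whose across-subject mean gray-matter
density exceeds an absolute threshold of 0.1 (a stricter "every subject
above threshold" variant is provided). For multi-cohort runs the
intersection of cohort masks is used so all maps share a grid.

## FWE control

Pooled analyses are thresholded at voxel-level family-wise error α = .05.
The implementation uses permutation max-T: the tested predictor column is
permuted (covariates and images fixed), each permutation is refitted via
the Frisch–Waugh–Lovell shortcut (covariates residualized out of the
response once; the permuted predictor residualized per permutation — this
reproduces the full-model t exactly), and a voxel's adjusted p-value is
(1 + #{null max statistic ≥ observed})/(1 + K). Bonferroni is available as
a fast deterministic option. Random-field-theory FWE (the SPM/CAT
convention) is not implemented; permutation FWE is exact under
exchangeability, and the substitution is noted in logs whenever FWE maps
are produced. No cluster-extent threshold is applied anywhere.

## ComBat harmonization

Scanner effects are removed with classic parametric empirical-Bayes
ComBat: features are standardized against a pooled model containing batch
indicators plus the biological covariates (CTQ sum, age, sex, TIV,
diagnosis); per-batch additive and multiplicative effects are estimated
per feature and shrunk across features (normal prior on locations,
inverse-gamma on scales, iterative posterior solution, convergence 1e-4);
data are batch-adjusted and re-scaled with covariate effects restored.
All six scanner groups enter one joint model by default (per-cohort
harmonization is a flag). The mask is computed from raw data before
harmonization and reused afterward. The implementation agrees with the
Bioconductor reference (`sva::ComBat`) to ~1e-5 on fixtures; with a single
batch the transform is the identity (there is no reference batch to adjust
against).

Note that EB shrinkage deliberately leaves per-feature residual batch
differences at sampling-noise scale (≈ √(2/n) per feature); what
harmonization removes is the systematic, across-feature batch effect, and
tests assert at that level.

## Replicability analysis

Cohort-wise maps are thresholded at uncorrected p < .001 and p < .01.
For every model and every cohort combination (three pairs + the triple),
the conjunction overlap k (voxels significant in *all* members) and, for
pairs, the Dice coefficient 2|A∩B|/(|A|+|B|) are computed (Dice is
undefined and flagged when both maps are empty). Under independent null
cohorts the per-voxel conjunction false-positive rate is αᵐ
(.01² = 1e-4, .001³ = 1e-9).

Significance of observed overlap: the tested predictor is permuted
independently within each cohort K = 1000 times, all cohorts' GLMs
refitted, maps re-thresholded and the overlap recounted, giving
p = (1 + #{null overlap ≥ observed})/(1 + K). The add-one estimator avoids
zero p-values and counts ties conservatively; with observed overlap 0 the
p-value is exactly 1. Freedman–Lane residual permutation is a possible
refinement but plain predictor permutation is the implemented scheme (and
is exact under the global null). The 72 permutation p-values
(18 models × 4 combinations) form one Benjamini–Hochberg FDR family per
threshold. Regional endpoints use per-model families of 155 tests
(14 subcortical + 140 cortical measures + global gray-matter density).

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, not brain
anatomy:

- **Cohort structure.** The default preset mirrors three adult cohorts
  (n = 1752 / 916 / 557; mean ages ≈ 35 / 35 / 52; 65/55/53% female;
  MDD fractions .47/.29/.42; medication-naive fractions among MDD
  .41/.14/.14) across six scanner groups. A `scale` parameter shrinks all
  cohorts proportionally for fast runs.
- **CTQ.** One standard-normal latent severity trait per subject; subscale
  latents load .80 on it; item latents load .85 on their subscale; items
  are discretized at z-cuts (0.65, 1.25, 1.85, 2.45). The cuts were
  calibrated once against coarse marginal targets — severe fraction ≈ 18%,
  none-to-minimal ≈ 38%, subscale medians near the scale minimum, strongly
  inter-correlated right-skewed subscales — and then frozen.
- **Confounding.** Diagnosis is drawn from a logistic link on the latent
  trait; the intercept is solved (bisection on the drawn sample) to hit the
  cohort's MDD fraction, and the default slope 1.8 is calibrated so the
  severe-vs-none odds ratio for MDD is ≈ 18 at the pooled diagnosis mix.
  Slope 0 gives an exactly unconfounded null.
- **Images.** voxel value = (radial template + age slope·(age−mean) + sex
  offset)·(TIV/1450 ml) + effect clusters + site additive shift + site
  scale·smoothed noise. Noise is white Gaussian (sd 0.25 before smoothing)
  filtered with σ = FWHM/(2√(2 ln 2)) per axis (default FWHM 8 mm at 4 mm
  voxels). Default grid 16³ — large enough for spatial structure, small
  enough for thousand-subject simulations on one CPU.
- **Effect injection.** A spherical cluster adds β·(x−x̄) with β calibrated
  from the target partial R²: β = ±√(r²/(1−r²))·σ_eff/sd(x_res), where
  σ_eff is the post-smoothing noise sd (exactly the white sd times the
  root of the sum of squared kernel weights) and x_res the predictor
  residualized on the generator covariates. Refitting recovers the target
  within sampling error (tests average a few seeds; the estimator
  t²/(t²+df) has a small positive bias at finite n). Direction defaults to
  negative.
- **Regions.** 140 cortical (split thickness/surface) + 14 subcortical
  endpoints with analogous covariate structure; TIV scales areal and
  volumetric but not thickness measures.

What the generator does **not** emulate: real anatomy, registration or
segmentation error, scanner physics, non-Gaussian intensity distributions,
spatially varying covariate effects, and site-by-covariate interactions.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the assumed data-generating structure, not
empirical claims about any real cohort.

## Simulation sizes and statistical checks

Simulation-based tests choose problem sizes so the checked property is
identifiable with comfortable margin: the empirical pairwise conjunction
rate uses 2×10⁶ null voxel-tests (4σ binomial band around 1e-4); the
permutation-overlap type-I check uses 200 replicates of two 40-subject
cohorts with 30 000 independent voxels at map threshold α = .05, so the
null overlap distribution is effectively continuous and the discrete
permutation p-grid (K = 200) is the only granularity; max-T FWE uses 200
null replicates with K = 99 (attainable level 4/100). Effect-recovery
checks use n = 500 per cohort, where an injected partial R² of .10 gives a
noncentrality around 7.5 against a p < .001 criterion (power ≈ 1), while
the small-effect non-replication check injects partial R² = .005 —
consistent with the magnitude of true brain-wide association effects —
where per-cohort power is a few percent and triple conjunction is
vanishingly rare.

## Numerical conventions

- float64 computation throughout; images float32 on disk (NIfTI), tables
  TSV, reports CSV, configs YAML, provenance JSON.
- All random stages take explicit seeds; generators are pure functions of
  (config, seed); permutation stages refuse to run without a seed.
- Design matrices are validated for full column rank before fitting, with
  collinear columns named (a single-sex subsample with a sex covariate is
  the canonical case, and the error says to use a stratified spec).
- BH adjustment is the standard step-up cumulative-minimum form, capped at
  1 (matches the statsmodels reference to 1e-12).
- χ² for the 2×2 contingency table uses no continuity correction, and the
  odds-ratio CI is Wald on the log scale with z = 1.959964.

## Limitations

- Permutation max-T and random-field-theory FWE agree only in the sense of
  both controlling voxel-level FWE; thresholds are not numerically
  identical.
- The Mann-Whitney p-value uses the normal approximation with tie
  correction (immaterial at the sample sizes involved).
- Non-parametric-prior ComBat and longitudinal variants are out of scope.
- The synthetic calibration targets are coarse marginal features, not
  claims about the distributions of any real cohort's data.
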