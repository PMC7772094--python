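# Methods

`sca1vol` implements a longitudinal volumetric-biomarker analysis for
spinocerebellar ataxia type 1 (SCA1): power-law adjustment of regional brain
volumes for intracranial volume (ICV), mixed-effects screens for
group-differential and within-group volume change, an estimator of the
earliest time at which change is detectable, penalized mixed-model selection
of motor-decline predictors, and a desk-scale multi-atlas label-fusion core.
Because the underlying MRI data are not redistributable, every stage is
exercised on synthetic data with known ground truth; this note records the
models, the defaults and why, and what the synthetic validation does and
does not establish.

## Synthetic cohort model

One row per subject-visit. For subject *i* of group *g* at elapsed time *t*
(years since that subject's baseline), region *r*:

    VOI_r(i, t) = alpha_r * ICV_i^beta_r * (1 + b_ir) + s_gr * t
                  + a_r * t^2 + e_irt

* **ICV** is drawn once per subject and held constant across visits
  (affected: mean 1 472 062.4, SD 116 358.8 mm^3; unaffected: mean
  1 535 453.8, SD 135 385.6 mm^3 — the emulated cohort's statistics).
* **b_ir ~ N(0, 0.05)** is a relative (multiplicative) subject intercept.
  Applying it on the power-law mean rather than additively in mm^3 keeps
  between-subject spread proportional to regional size and avoids
  confounding the intercept with ICV. The 5% default yields raw VOI-ICV
  correlations around 0.6–0.9, inside the range such cohorts report.
* **s_gr** is the linear atrophy rate. Unaffected subjects default to zero
  change; affected-group defaults are the cohort-scale group-by-time
  contrasts for all 34 regions (e.g. pons −348.1, putamen −136.8, caudate
  −106.2 mm^3/yr; `sca1vol.regions`). The quadratic term `a_r` defaults to
  zero and is exposed for accelerating-decline scenarios.
* **e_irt ~ N(0, sigma_r)** is per-visit measurement noise. `sigma_r =
  5.55 * SE_r`, where SE_r is the reported precision of region *r*'s
  group-by-time contrast. The constant 5.55 was calibrated once by Monte
  Carlo so that the simulated screen reproduces that reported precision at
  cohort scale (13/20 subjects, visits 0/1.5/3.0 years): with it, the
  simulated pons contrast has mean SE 40.4 against the reported 40.7 and
  denominator df ≈ 61 against the reported 59.9. It was frozen before any
  acceptance measurement and is not revisited.
* **Design**: visits at 0/1.5/3.0 years, follow-ups jittered N(0, 0.1 yr)
  (baseline anchors t = 0 exactly); each affected subject independently
  misses visit 3 with probability 3/16; at most 15 unaffected subjects are
  invited back for visit 3. Gender is Bernoulli with group rates 8F/5M and
  8F/12M and has no true effect, so covariate adjustment is testable as a
  null. Baseline age ~ N(53, 9) years in both groups.

**SARA.** Baseline scores are drawn per subject (affected mean 7, unaffected
0.5, SD 3) and change at follow-ups as

    dSARA(t) = c_pons * dPons(t) + c_put * dPutamen(t) * t + noise,

clamped to the instrument's [0, 40]. The second term is written as the
change-by-time interaction column itself because a rate-of-change effect of
the putamen is exactly what that interaction encodes in the selection
design; a literal "rate times elapsed time" product algebraically collapses
to the main effect and could never be distinguished from it. Defaults
`c_pons = −0.00272` points/mm^3 and `c_put = −4e-4` points/(mm^3·yr) make
volume loss raise SARA; SARA noise SD defaults to 1.0 point (test-retest
scale).

**What the generator does not emulate**: baseline volume deficits in the
affected group (both groups share the power-law mean, so the baseline
screen runs as a null check on synthetic data), realistic MRI appearance,
registration error, non-Gaussian measurement error, and floor effects in
severely atrophied regions. Passing tests therefore establish the
*statistical machinery* — calibration, recovery, invariances — under the
assumed generative structure, not the clinical conclusions of any real
cohort.

## ICV adjustment

Per region, `VOI = alpha * ICV^beta` is fit by least squares, the region is
adjusted as `VOI / ICV^beta`, and the adjusted values are mapped back to
natural units by `((adj − mu_adj)/sigma_adj) * sigma_raw + mu_raw`
(population moments, computed over the same pooled sample as the fit, so
the rescaled values match the raw mean and SD exactly).

The default estimator works on the **log scale** (closed-form log-log
regression). Under multiplicative error — the realistic structure for
volumes, and the generator's — this is the maximum-likelihood fit, and its
in-sample residual orthogonality is what drives post-adjustment VOI-ICV
correlations to the ±0.03 range. Original-scale nonlinear least squares
(Levenberg–Marquardt, warm-started from the log fit, relative tolerance
1e-8, ≤200 iterations) is retained as `method="original"`; its residuals
are orthogonal in the raw-mm^3 metric instead, which leaves in-sample
correlations as large as ~0.1 at 33 subjects however small the noise, so it
is not the default. Both are exact on noise-free power-law data.

The fit pools all subjects, groups and visits (adjustment precedes all
group analyses); `baseline_only=True` restricts it to visit-1 rows.

Note that rescaling to the raw moments stretches within-subject changes by
`sigma_raw / (sigma_adj * ICV^beta)`-type factors: slopes estimated from
adjusted volumes are on the adjusted-natural-unit scale, not the raw
generative scale. Parameter-recovery simulations therefore run on
unadjusted cohorts.

## Mixed-effects screens

All longitudinal screens model **change from baseline** (delta of the
region, zero at the baseline row by construction) with a subject random
intercept; baseline rows are included, which anchors the intercept near
zero and matches denominator df around 60 for 33 subjects. Age at testing
is decomposed into baseline age (between-subject) and change in age
(within-subject) so the two enter independently.

* Group screen: fixed effects group + time + group×time + baseline age +
  gender; the focal term is the interaction. Unaffected is the reference
  level (negative interaction = faster loss in SCA1); gender reference is
  male.
* Within-affected screen: time + baseline age + gender on the affected
  subset; focal term is time.
* Baseline comparison: OLS of the z-scored baseline volume on group +
  baseline age + gender; the group coefficient is a standardized effect in
  SD units with a 95% t-interval.

The random-intercept model is fit by REML with the criterion profiled to a
one-dimensional search over the variance ratio (bounded Brent on the log
scale, tolerance 1e-10; the zero-variance boundary is accepted when it
scores at least as well). Denominator df use a Satterthwaite approximation:
`df = 2 f^2 / (grad f' Cov(theta) grad f)` with `f = l' Cov(beta) l`,
gradient and REML Hessian by central finite differences over the two
variance components (relative step 1e-4). Against lmerTest on a shared
dataset the fit agrees to ~1e-6 in coefficients and ~1e-3 in df; at the
boundary the df fall back to the residual n − p. The df method is
config-exposed (`df_method="residual"` for the classical choice).
Family-wise error uses Bonferroni with m = 34, the screened-region count
(m is an argument everywhere).

Non-convergence and rank-deficient designs raise; `screen_all` flags the
failed region and completes the rest.

## Detectability horizon

From the within-affected fit, the predicted cumulative change is
`c(t) = b0 + b_t t` with `Var[c(t)] = v00 + 2 t v0t + t^2 vtt` from the
fixed-effect covariance. The horizon is the smallest t in (0, 5] years at
which the two-sided CI (default 99%, critical value from the t distribution
with the fit's Satterthwaite df) excludes zero, found by a 501-point grid
scan plus bisection to 1e-4 yr. A quadratic closed form for the boundary
crossing serves as the independent check (they agree to <1e-3 yr across
random draws). A phrase like "the CI of the elapsed-time effect no longer
overlaps zero" could also be read as a statement about the slope alone;
that reading is time-invariant (detectable at every t or never) and is
implemented as `method="slope-ci"`. Only the fixed-effect covariance enters
by default — which variance components a given study folds in is rarely
stated — so computed horizons are comparable within an analysis but not
across pipelines; on synthetic cohorts they land at 1–4 years for the
strong regions, longer than the 0.5–1.0 yr a tightly-measured clinical
cohort can report.

## Penalized mixed-model selection

The selection stage models dSARA at follow-up visits with penalized fixed
effects for each candidate region's change and its change-by-time
interaction, plus elapsed time, baseline age and gender (all penalized by
default; the intercept never), and a subject random intercept:

    maximize  loglik_ML(beta, s2_b, s2_e) − lambda * sum_j |beta_j|

on unit-SD-standardized columns (constants stored; reported coefficients
are back-transformed to raw units). The solver alternates coordinate
descent with soft-thresholding on group-whitened data (the random-intercept
covariance has a closed-form inverse square root) with profiled ML updates
of the variance components; the penalized objective is monotone across
sweeps and convergence is declared at 1e-8 relative change. At lambda = 0
the solution matches an independent mixed-model ML fit to ~1e-4 relative;
at saturating lambda every penalized coefficient is exactly zero.

The integer grid lambda = 1..100 is traversed with warm starts from the
sparse end; each lambda records `BIC = −2 loglik + k log n` with k = active
fixed effects + 2 variance components, and lambda* minimizes it (smallest
lambda on ties). Subject-grouped K-fold cross-validation (never splitting a
subject) reports held-out fixed-effect prediction MSE per lambda alongside.

**Support selection.** Change scores of co-atrophying regions are strongly
collinear, and with two follow-up visits each region's change and its
change-by-time interaction correlate at ~0.92. Under such collinearity the
raw active set at lambda* is a poor support estimate: shrinkage bias on the
strong true terms drags correlated extras into the path (measured ~30%
exact recovery under the generative SARA model at 200 subjects). The
report therefore treats the path as a candidate generator: every distinct
active set along it is re-fit by unpenalized ML and scored by the extended
BIC `−2 ll + (k+2) log n + 2·0.5·k·log p` (the log-p term prices the choice
among p candidate columns), and the best set is greedily backward-pruned
under the same score. Measured on 100 replicates this yields 99% exact
recovery, versus 88% with the plain log-n penalty and ~30% for the raw
lambda* set; `criterion="lambda-star"` restores the raw behavior. The
documented recovery conditions are 200 affected subjects, full follow-up,
SARA noise SD 0.5 points, default volumetric noise.

Inference on the selected support is naive post-selection Wald inference
(z from the refit information); it ignores the selection event, is
anti-conservative, and says so with a warning.

## Label fusion

Exemplar selection correlates Jacobian-determinant maps (Pearson) inside
the brain mask, on the **log scale** by default since determinants are
ratio-scaled (raw-scale option retained); NaN from a zero-variance map
warns and ranks last; ties break by candidate order. Fusion gives every
label set of every chosen exemplar one vote per voxel, weighted by
`1/(1e-6 + mean squared intensity difference over a 3^3 patch)` between
that candidate's intensity image and the target; argmax with
lowest-label-code tie-break; out-of-mask voxels are background. Defaults
k = 10 exemplars and 5 label sets each (50 labelled images). Inputs must
already be grid-aligned — registration is out of scope and validated as a
precondition. Volume extraction is voxel count × voxel volume; per-region
volumes sum exactly to the labelled ICV.

The synthetic atlas stack controls exactly the features these steps depend
on: the sample correlation of each candidate's log-Jacobian map with the
target's is set *exactly* by Gram–Schmidt construction, and label maps
deviate from a shared ground-truth Voronoi parcellation at a configurable
rate. It makes no attempt at MR realism.

## Problem sizes and numerical checks

Validation uses 1000 null replicates and 500 recovery replicates at cohort
scale (33 subjects) for screen calibration, 100 replicates at 200 subjects
for support recovery, 100 random coefficient/covariance draws for the
detectability solver, 32^3 voxel grids for fusion, and 20 random designs
for the lambda = 0 equivalence; `scripts/acceptance.py` recomputes all of
these from scratch. Degenerate inputs (constant responses, zero-variance
maps, non-positive volumes, missing baselines, rank-deficient designs)
raise informative errors rather than propagating silently.

## Known limitations

* The generator's linear-trajectory, Gaussian-noise world is favorable to
  the fitted models; real cohorts bring floor effects, heavier-tailed
  measurement error and informative dropout.
* Post-selection p-values are anti-conservative by construction.
* Detectability horizons depend on which variance components enter the CI;
  the default (fixed-effect covariance only) is one defensible choice.
* The label-fusion core implements similarity-weighted voting, not the full
  joint-covariance weighting of published joint-label-fusion estimators,
  and consumes pre-registered inputs.
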