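# Methods

This note records the statistical and numerical choices behind
`holctract`: what each stage assumes, which knobs matter, what the
synthetic data do and do not emulate, and where the design was genuinely
open.

## Exposure assignment

All geometry is planar. The package performs no reprojection and no
geodesic arithmetic; inputs must already be in a consistent equal-area
projection, and areas are taken in the squared coordinate unit. Polygons
that fail validity are repaired with a buffer-free validity fix and
rejected if the repair fails.

The area-overlap rule unions all polygons of a grade before
intersecting, so seams between adjacent same-grade polygons cannot
double-count. Polygons of *different* grades are assumed disjoint; a
violation is reported as a warning with the overlapped area, and each
grade's fraction is still computed against its own union.

The coverage threshold (default 0.25, sensitivity 0.50) tests the
**total** graded coverage, summed over all five grades including E,
because the filter logically precedes grade assignment: a tract barely
touched by the graded map is not analyzable regardless of which grade
wins. Grade E can win the argmax; such tracts are excluded explicitly at
assembly, never silently reassigned to A–D.

Ties in the argmax (measure-zero on real geometry, exact on aligned
synthetic grids) break toward the more desirable grade in the fixed
order A < B < C < D < E. This is deterministic and conservative against
finding adverse effects of less desirable grades. The same order
resolves a centroid that falls exactly on a shared boundary. The
centroid rule uses the geometric centroid even for non-convex tracts
whose centroid falls outside themselves.

## Missing data

Hypertension prevalence may be missing; diabetes and obesity may not.
Analyses are complete-case **per outcome**: a tract missing only
hypertension contributes to the diabetes and obesity models, so the
three outcomes legitimately have different Ns. In the causal chain,
propensity fitting and trimming use all tracts of a pair (outcomes play
no role there); outcome missingness is applied after trimming. The
assembly step records a provenance count after each exclusion (coverage
threshold, grade-E removal, covariate join, outcome join), and the chain
is checked to be monotone non-increasing.

## Exploratory OLS

The grade contrasts use ordinary least squares with classical
homoskedastic standard errors by default; a heteroskedasticity-robust
(HC1) option exists but is off, since the exploratory tables are meant
as descriptive contrasts. Confidence intervals are estimate ± 1.96·SE
throughout the package (normal approximation; all analysis Ns are in the
hundreds or thousands, where the t correction is negligible). Region
enters as indicators with Midwest (alphabetically first) as reference;
the 1940 covariates enter untransformed in their original units.
Rank-deficient designs are an error naming the collinear columns
(identified by QR with column pivoting), not a silent drop.

## Propensity scores

The logit is fitted by Newton/IRLS on internally standardized
covariates (for conditioning), with coefficients transformed back to
original units; convergence requires a maximum absolute coefficient step
below 1e-8 within 100 iterations. The fitted model always has 12
coefficients: intercept, eight sociodemographics, three region
indicators.

Separation handling deserves a note. Under (quasi-)complete separation
the ML estimate diverges, so the Newton step never falls below the
tolerance — the fit fails with an error advising inspection, never a
silent clamp. A **converged** fit, by contrast, is a finite MLE, and an
extreme fitted score there is information, not pathology: a tract that
was 90% Black in 1940 is classified grade D almost surely, and such
tracts exist in real data. These extreme-but-interior scores are exactly
what the trimming step exists to remove, so they are left to it. The
only post-convergence error is a score reaching exact 0/1 in floating
point, which would break the inverse weights.

## Trimming, weights, MSM

Trimming bounds are the alpha and 1−alpha quantiles
(linear-interpolation definition, inclusive bounds) of the **pooled**
score distribution of the pair — pooled rather than per-arm because the
procedure treats the pair's score distribution as one object; the
per-arm alternative is a known variant and the choice is surfaced as a
parameter. Retention below 50% is an error flagging pathological
overlap. Default alpha 0.025.

Weights are unstabilized ATE weights w = Z/e + (1−Z)/(1−e) by default.
Since the structural model contains no baseline covariates,
stabilization cannot move the point estimate — it only tames the weight
distribution — so it is an option (`weight_type="stabilized"`, arm
prevalence numerators followed by normalization to overall mean 1)
rather than the default. Effective sample sizes (Σw)²/Σw² per arm are
reported as diagnostics.

The MSM is weighted least squares of outcome on intercept + treatment;
its coefficient equals the difference of weighted arm means exactly
(identity tested to 1e-10). The variance is the HC0 sandwich
(X'WX)⁻¹(Σᵢ wᵢ²eᵢ²xᵢxᵢ')(X'WX)⁻¹ with weights treated as fixed —
standard MSM practice, mildly conservative because it ignores the
estimation of e(x). Note this is *not* what a WLS routine's "HC0" option
returns (that is the sandwich of the √w-whitened model), which is why
the four-line sandwich is computed explicitly. A nonparametric bootstrap
(resample tracts, re-fit propensity, re-trim, re-weight; percentile CI;
default B = 1,000, seeded) is provided because the appropriate CI for a
trimmed, estimated-weight estimator is genuinely debatable.

## Full matching

The sensitivity estimator is a deliberately simple greedy full matching,
not optimal full matching: sort by score, seed one set per minority-arm
unit, attach each majority-arm unit to its nearest seed by absolute
score distance. A seed left without any majority unit is folded into the
set of its nearest majority-arm unit, so every set contains both arms.
Within a set, minority units carry weight 1 and majority units the set's
minority/majority ratio; majority-arm weights are then rescaled to sum
to that arm's retained size. Its acceptance is balance improvement and
agreement with the IPW estimate on synthetic data — equality with any
external optimal-matching implementation is explicitly not claimed.

## Balance diagnostic

SMD = (treated mean − control mean) / pooled SD, with the **unweighted**
pooled SD √((s²_T + s²_C)/2) as denominator for both the weighted and
unweighted versions, so the two are on the same scale. Zero pooled SD
yields SMD 0 with a warning flag.

## Synthetic data

The generator exists to give every stage a testable ground truth, not to
impersonate any real city.

*Geometry.* Tracts are unit squares on an n×n grid; graded areas are
axis-aligned rectangles (vertical stripes or a block grid) cycling
through grades A–E with an ungraded gap, edges jittered so tract and
grade boundaries misalign. Overlap fractions have closed forms
(rectangle intersections), emitted as an oracle table; the stripes
layout varies the winning grade only per column, so the block layout is
the default for study-like runs.

*Covariates.* Grade-conditional distributions target the real study
area's published 1940 means and SDs. Numerical choices, each made once:

- Most percentages are truncated normals on [0, 100]. The parent
  parameters are calibrated so the generated mean matches the target
  *exactly* (1-D root solve); the SD is matched by least squares where
  feasible — a left-truncated-at-zero normal cannot have SD much above
  its mean, so the most skewed targets keep the mean but a smaller SD.
- The percent-Black family, home value, and density are right-truncated
  lognormals (caps 100%, $30k, 80 k/km² — 1940-realistic ranges),
  preserving the targets' coefficient of variation and hence their
  heavy right skew; means again calibrated exactly. Percent non-White is
  percent Black plus a non-negative increment, so the subset invariant
  holds by construction.
- Within a grade the eight covariates co-move through a one-factor
  Gaussian copula (loadings ±0.5–0.7; disadvantage-aligned signs) whose
  scores are winsorized at ±3. Independent draws would make the grades
  far more multivariately separable than real tract samples — separable
  enough to break any propensity fit — and joint 4-sigma tracts do not
  occur in real data. Means are re-calibrated exactly under the
  winsorized scores.
- 10% of tracts are "lookalikes" drawing their covariate vector from an
  adjacent grade (transitional or arguably misgraded neighborhoods),
  with the per-grade targets pre-adjusted by a linear solve so the
  observable grade-conditional means still match the stated values
  exactly.
- Regions are drawn from the study area's region-by-grade table,
  independently of covariates given grade.

*Assignment and outcomes.* Pair scenarios assign treatment by a Bernoulli
draw from a logit on (standardized) covariates — the exact model the
propensity stage fits, so the estimator is evaluated under correct
specification. Outcomes are continuous tract-level prevalences (the
analyzed data are modeled tract prevalences, not individuals):
baseline + coefficients·standardized covariates + effect·treatment +
Gaussian noise, clipped to [0, 100] with clip events counted (the
defaults keep clipping under 1%). Hypertension missingness is
completely-at-random at 3% — the real missingness is geographic
(state-level), which is out of scope to emulate, so tests involving
missingness say nothing about geographically structured gaps.

*Scenarios.* `confounded` (true effect 1.0; assignment and outcome both
loaded on unemployment, percent Black and home value, giving the crude
contrast an upward bias of roughly +3 points), `null` (same confounding,
effect 0), `unconfounded` (random assignment), and `table1-like` (all
four grades, covariates conditional on grade, known step effects between
adjacent grades, hypertension missingness). In `table1-like` the
treatment mechanism is *not* a logit — grades come first and covariates
follow — so the propensity model is misspecified by construction there;
contrasts whose covariate distributions differ most non-linearly
(D vs C, dominated by the skewed percent-Black gap) retain visible
residual confounding. That is an honest property of the emulation, and
it is why the estimator's recovery and calibration claims are
established on the correctly-specified pair scenarios, at n = 4,000 with
200 (recovery) and 500 (null calibration) replicates — sizes chosen to
make Monte-Carlo error small relative to the tolerances while keeping
the default test run short.

*What passing tests do not show.* The generator has no spatial
autocorrelation in covariates or outcomes, no measurement error in the
historical covariates, no geographic missingness, and real HOLC polygons
are not rectangles; passing tests validate the estimator chain's
algebra, calibration under correct specification, and its geometric
primitives — not robustness to those real-data features.

## Pipeline

A run is a `RunConfig` (YAML-loadable); outputs are plain CSVs plus a
text log, and reruns with identical config and seed are byte-identical.
Any stage error removes partial outputs and aborts with the stage name.
The default RNG seed is 20240301, and every stochastic API takes an
explicit seed. The CLI (`link`, `simulate`, `analyze`, `compare`) is a
thin wrapper over the library; exit codes are 0 (success), 2 (config
error), 3 (data error).

## Known limitations

- The 2020→1940 crosswalk attaches each modern tract to the single 1940
  tract containing its centroid; no areal weighting of 1940 covariates
  across multiple parents is attempted.
- Classical OLS SEs in the exploratory tables ignore spatial dependence,
  as do the HC0 MSM SEs.
- The greedy full matching approximates, and will generally differ
  from, optimal full matching.
- Trimming changes the estimand unless effects are homogeneous (they
  are, in the generator).
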