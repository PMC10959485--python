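# Methods

## Scope and data model

`clinesel` analyzes maternal half-sib common-garden trials at the family
level. The observation unit is a seedling with design factors (family,
population, optional subpopulation, block, trial year), greenhouse traits
(budset timing in days, first-year height in mm, ordinal fall frost injury
0–4), and a field survival/height history; families carry origin
coordinates and the weight of a 200-seed sample. Two CSV files
(`seedlings.csv`, `families.csv`; empty cell or `NA` = missing) are the
only external format. The loader never converts units — greenhouse heights
are mm, field heights m, as declared. Validation marks out-of-range values
(`ffi_score` outside 0–4, non-positive budset days, negative heights,
non-binary survival flags) as excluded with reason `range` rather than
dropping them silently. Seedlings noted dead or unhealthy in the greenhouse
and unidentifiable field trees are removed by configurable exclusion rules;
a tree missing at the final census is scored dead, which also forces its
dead-inclusive height to 0. A seedling that never formed a terminal bud is
encoded as missing `bst_days` plus a `no_budset` flag, so the downward bias
this causes in late-budset populations can be reproduced or avoided
deliberately.

## Mixed model and heritability

The family model `Y = m + block + family + error` (plus a fixed population
effect in multi-population fits) is fit by REML. Because the model has a
single grouped random intercept, the fit profiles the restricted likelihood
over the variance ratio `r = sigma2_f / sigma2_e`: per-family sufficient
statistics give the GLS fixed effects, the residual variance and the
restricted criterion in closed form for each `r`, and a bounded
one-dimensional search (tolerance 1e-12 on log `r`) maximizes it over
`r >= 0`, accepting the boundary (no negative components). On balanced
single-block data this reproduces the ANOVA method-of-moments estimator to
relative 1e-6 and the closed-form BLUP shrinkage
`(n sigma2_f / (n sigma2_f + sigma2_e)) (family mean - fitted mean)` to
1e-8; both identities are enforced in tests, and a statsmodels `MixedLM`
fit serves as an independent cross-check on unbalanced multi-block data.

Under the half-sib assumption (open-pollinated progeny share only the
mother; no maternal effects; unrelated mothers) `V_A = 4 sigma2_f`.
`V_P = sigma2_f + sigma2_e` excludes the fixed block/population variance —
the definition consistent with treating blocks as a nuisance design factor.
`Var(sigma2_f)` for the Dickerson heritability SE,
`SE(h2) = sqrt(16 Var(sigma2_f)) / V_P`, comes from the observed
information of the restricted likelihood in `(sigma2_f, sigma2_e)`
(central finite differences at the optimum); for the balanced ANOVA oracle
the classical mean-square sampling variance is used instead. The source is
recorded in the output, and the SE is flagged missing (never fabricated) at
the boundary. Fixed effects use treatment coding with the first block as
reference; BLUP centering is unaffected by this choice. The ordinal frost
score is analyzed on the linear scale, treating the underlying damage
phenotype as continuous.

Family estimates are exposed on three scales: deviations `f_j` (mean ~0),
centered estimates `m + f_j` with `m` the grand fixed-effect mean, and
population-inclusive estimates `m + f_j + p_k`.

## Correlations

Genetic correlations are Pearson correlations of family estimates, not
multivariate REML — deliberately, since family estimates are the study's
unit of inference throughout. Four aggregation levels are distinguished:
within the focal population (focal BLUP deviations), pooled within the
latitudinal populations (centered estimates, population effects removed),
between populations family-wise (population-inclusive estimates), and
between population means. Confidence intervals use the Fisher z-transform
with SE `1/sqrt(n-3)`; p-values the `t = r sqrt((n-2)/(1-r^2))` reference.
`|r| = 1` yields a clamped, flagged interval. Phenotypic correlations are
seedling-level and pairwise-complete. Variance inflation factors come from
the inverse trait correlation matrix (identical to the regression
definition `1/(1-R^2)`, verified in tests); perfect collinearity reports
infinite VIF with a warning. The subpopulation contrast is a classical
equal-variance Student's t (Welch optional).

## Selection-surface analysis

Traits enter the selection analysis as focal-population family estimates
plus family seed weight, standardized by their SDs. The pipeline centers
before scaling: BLUP deviations are already near zero-mean, and centering
seed weight anchors the quadratic model's linear coefficients and the
index-variable ranges at the trait means (centering changes `beta*`, never
`beta` or `gamma`). Relative fitness divides by mean absolute fitness, so
`mean(w) = 1` exactly, for both fitness definitions (family BLUP of age-9
height including dead trees at height 0; family survival proportion). If
the fitness REML collapses to zero family variance, the pipeline falls
back to raw family means with a warning — shrunken BLUPs would otherwise be
identically zero and the regression undefined.

Directional gradients come from the linear-only OLS model; quadratic and
correlational gradients from the full second-order model, with the
squared-term coefficients doubled for reporting (an OLS fit of
`w ~ f + f^2 + f_i f_k` estimates `gamma_ii / 2` on the squared terms);
SEs are doubled with them, leaving t statistics untouched. Classical OLS
standard errors are used throughout (no robust correction), and
significance is annotated at p < .10/.05/.01/.001 without multiplicity
correction. Mardia's multivariate skewness and kurtosis statistics (ML
covariance; chi-square and normal references) document departures from
multivariate normality that motivate the two-step fit.

The surface matrix `Gamma` supports two recorded conventions: `halved`
(default; diagonal `gamma_ii/2`, off-diagonal `gamma_ik/2`), whose
quadratic form reproduces the fitted surface and whose eigenvalues are the
canonical curvature gradients on the regression scale, and `full`, which
doubles every entry and hence every eigenvalue. Canonical analysis sorts
eigenvalues descending, fixes each eigenvector's sign so its
largest-magnitude loading is positive, breaks exact ties by original axis
index (flagged), and verifies `M' M = I`, the reconstruction
`M diag(lambda) M'`, and the trace identity at machine precision.
Significance of `theta` and `lambda` comes from re-fitting the full
quadratic regression on the index variables `z = M' f` (cross terms
included; they are estimated near zero by construction). The stationary
point is `z* = -theta/(2 lambda)` per axis, with zero-eigenvalue axes
flagged undefined; published tables of this analysis sometimes print `z*`
values orders of magnitude smaller than this formula yields from the
printed `theta` and `lambda` — the formula is implemented as defined, and
the fitted-surface gradient is verified to vanish at `z*`.

## Synthetic trials and calibration

The generator draws, per population, zero-mean multivariate family effects
with covariance `G` (the between-family component, `V_A/4`; fathers are
never simulated), adds a clinal population mean (linear in latitude),
shared block effects, and multivariate residuals `E`; frost injury is
thresholded from its latent value (score = number of cut points strictly
below). Defaults are the study conditions of a Scots pine provenance
trial: a focal population of 500 families × 24 seedlings in 6 blocks plus
five latitudinal populations (latitudes 50.7–67.2°N) of 10 families × 12.
Calibrated default values:

* cline intercepts/slopes: least-squares fits of published population means
  on latitude (BST −1.67 d/°N, FYH −2.31 mm/°N, latent FFI −0.20/°N, seed
  weight −0.015/°N);
* `G`/`E` diagonals: the published focal-population scale (BST 10.1/73.5,
  FYH 35.4/214.9, latent FFI 0.0675/0.7625 → true h² 0.483/0.565/0.325);
  `G` correlations 0.14/0.19/0.35 (the published within-focal estimates),
  0.05 with seed weight; residual BST–FYH correlation 0.24 so the
  seedling-level phenotypic correlation lands at ~0.23 (same-trial traits);
  frost-injury and seed-weight residuals independent;
* frost thresholds: latent mean + SD × (−1.45, −0.37, 0.58, 1.58), putting
  the focal score mean at ~1.9;
* block SDs (1.5 d, 4 mm, 0.1 score units; none for seed weight) and the
  seed-weight scale (mean ~1.2 per 200 seeds, family SD 0.15) are not
  published and were chosen once as realistic for greenhouse pine trials;
* fitness: the published family-level height-definition gradients as the
  true surface on the standardized family scale, family-level noise SD 0.15
  (unexplained real fitness variation — large relative to the surface
  terms, and necessary for the family variance of the fitness proxy to be
  estimable at all), random early mortality 0.25 and a survival scale of
  0.85, reproducing the published survival trajectory (~93/71/64% across
  the three censuses); survivor heights are drawn around 2.46 m
  independently of the surface, so both fitness definitions have expected
  relative fitness proportional to the same surface value.

Everything is deterministic given the seed (one `numpy` Generator;
recorded values stable well below 1e-9).

What the generator does *not* emulate: the real two-sowing design (frost
injury was scored on different seedlings than budset/height — simulated
seedlings carry all traits, though a shared-vs-independent residual switch
covers the statistical consequence), explicit pollen flow or paternal
structure, spatial autocorrelation within blocks, multi-year growth
dynamics, and selective (trait-dependent) early mortality beyond the
surface itself. Passing recovery tests therefore demonstrate estimator
correctness under the assumed generative model, not robustness to these
real-data complications.

A consequence worth noting for end-to-end runs: gradients re-estimated
from re-fitted fitness BLUPs are attenuated relative to the generator's
truth, because shrinkage compresses both the fitness and the trait
estimates. This mirrors the real analysis — published family-level
gradients are themselves on the shrunken-BLUP scale — so estimator
validation uses the direct route (true standardized family values in,
gradients out), where recovery within ±3 SE is enforced.

## Numerical choices and degenerate inputs

* REML: bounded Brent on log variance ratio, `xatol` 1e-12; boundary
  accepted; constant-response data short-circuits to zero components.
* Eigen-decomposition via `numpy.linalg.eigh` (symmetric); asymmetry beyond
  1e-12 is a contract error; near-degenerate eigenvalue pairs (gap below
  1e-12 × spectral radius) are flagged.
* Fisher intervals clamp at `|r| = 1`; zero-variance inputs raise.
* Fitness must be non-negative; surface draws below zero are floored at 0
  and counted.
* CSVs are written with 17 significant digits and parsed with correctly
  rounded `float()`, so write→read round-trips are bit-exact.

## Problem sizes

Recovery tests run at the study design size (500 × 24) where that is the
claim (mean REML h² over 100 replicates within ±0.03 of truth; empirical
SD consistent with the ~0.04–0.05 SE scale) and at reduced sizes (40–100
families) for identities that hold at any size. Moment checks on the
generator use 2000 families. The full pipeline on a study-size trial runs
in about a second on one core.
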