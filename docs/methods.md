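# Methods

This document describes the statistical model, the synthetic-data generator,
and the numerical choices behind `volunteerbias`.

## 1. Problem

Volunteer cohorts are not random samples. People who respond to an invitation
to join a study differ systematically from those who do not — they tend to be
healthier, better educated, and more settled — and participation typically
depends on *combinations* of traits, not just one at a time. Associations
estimated inside such a cohort therefore mix the relationship of interest
with the selection mechanism. The distortion can be large enough to flip the
sign of an association, and adding the selection-related variables as
regression controls does not fix it: conditioning on (a descendant of) the
selection indicator is a collider adjustment and can create bias of its own.

The correction implemented here is inverse-probability weighting against a
population-representative reference sample: estimate each volunteer's
conditional probability of being in the cohort rather than in the reference,
and weight cohort members by the inverse odds of that probability. Weighted
estimates then consistently recover the eligible-population associations,
provided the participation model conditions on the drivers of selection and
every eligible person has positive participation probability.

## 2. Data model

All variables are categorical and described by a `Codebook`: levels, optional
numeric scores per level (used for standardized analyses and SD diagnostics),
raw-source recode maps, and eligibility rules (age bands and region). Person
tables are plain data frames with a `person_id`, a `source` column
(`cohort` / `reference`), and one column per variable. Harmonization recodes
raw files into codebook levels (unmapped values become missing and are
counted), then filters to the eligible population.

## 3. Synthetic population generator

The generator exists so the correction can be validated against a known
ground truth.

* **Dependence.** A Gaussian copula: latent standard-normal vector with a
  specified correlation matrix (checked for positive semi-definiteness via
  its smallest eigenvalue), discretized per variable at normal quantiles of
  the cumulative level probabilities. This gives arbitrary categorical
  margins with controlled cross-variable dependence.
* **Reproducibility.** All randomness flows from one integer seed through
  named `SeedSequence` spawn streams (`population`, `reference`,
  `selection`, `missingness`), so changing one stage never perturbs another.
* **Participation.** A probit on the level dummies with main effects *and
  two-way interaction effects*. The intercept is solved by `brentq` so the
  population participation rate hits a configurable target (default 5.5%).
  Each person's true participation probability is retained (`true_prob`), so
  ground-truth "oracle" weights `1 / true_prob` are available for
  validation.
* **Reference sample.** A simple random sample of the eligible population
  (default 5% sampling fraction) thinned by a response rate (default 95%) —
  representative by construction, as a population register survey would be.
* **Missingness.** Missing-completely-at-random per variable at low,
  survey-realistic rates.

### Why interactions drive the default calibration

With a mains-only probit in which both older age and poor health raise (or
lower) participation monotonically, selection shifts levels but does not
reverse the sign of the age → poor-health association; truncation on a sum
of positive main effects tends to *strengthen* a positive association. A
sign reversal requires participation to fall off specifically for the
joint combination — old *and* in poor health — which is exactly an
interaction effect, and is also the empirically plausible mechanism (healthy
volunteer bias is strongest among the old). The default selection
specification therefore puts modest main effects on each trait (calibrated
so the one-way cohort margins look like a typical volunteer cohort: older,
healthier at fixed age, more educated, more likely home-owning and white)
and concentrates the distortion in two-way interactions (age × health,
age × employment, health × car ownership, education × employment,
tenure × car ownership, cars × household composition). This produces
pervasive bias across many pairwise associations, including one full sign
reversal, while keeping margins realistic.

## 4. Participation weights

1. **Stacking.** Cohort (label 1) and reference (label 0) rows are stacked.
   Missing values are imputed per source by exact-match hot deck: donors
   share every observed value of the recipient's missingness pattern;
   recipients with no exact donor are excluded (and reported).
2. **Design.** Level dummies for all model variables plus *all* two-way
   interaction dummies, pruned of constant and duplicate columns. For level
   counts `L_k` the unpruned width is `sum L_k + sum_{k<l} L_k * L_l`.
3. **L1-penalized probit.** The participation model is fit by proximal
   gradient descent (FISTA) with backtracking line search and
   gradient-based adaptive restart, wrapped in a working-set outer loop;
   the intercept is never penalized. Convergence is declared at a KKT
   residual below 1e-6. `lambda_max` is the exact KKT entry point (the
   smallest penalty at which all coefficients are zero); the grid is
   geometric from `lambda_max` down to `lambda_max * 1e-4` in 14 points.
   The wide design (hundreds of sparse interaction columns) is why an L1
   path, rather than a fixed hand-picked model, is the core primitive.
4. **Cross-validation.** Stratified K-fold (default 5) on held-out probit
   deviance; the penalty minimizing mean held-out deviance is chosen and
   the final path is refit on all data down to that penalty.
5. **Post-selection refit.** By default the CV-selected active set is refit
   *without* penalty (`refit_active_set`). L1 shrinkage attenuates
   coefficients toward zero, which systematically mutes the estimated
   participation probabilities and hence under-corrects the weights; the
   unpenalized refit removes that attenuation while keeping the selected
   sparsity.
6. **Weights.** With fitted probability `pi` of being a cohort row within
   the stacked sample, the weight is the inverse odds `(1 - pi) / pi`.
   Because the reference is representative, the stacked-sample odds of
   cohort membership given covariates are proportional to the
   participation odds, so inverse odds are proportional to inverse
   participation probability; the proportionality constant is absorbed by
   mean-one normalization. A direct `1 / pi` variant is available
   (`formula="inverse-probability"`). Probabilities are clipped to
   `[1e-8, 1 - 1e-8]` and clipping is counted; extreme-weight flags and
   overlap checks are reported.
7. **Separation heuristic.** At zero penalty, any coefficient exceeding 8
   in absolute value triggers a separation warning — on the probit scale
   that corresponds to fitted probabilities below ~1e-15, i.e. numerically
   flat likelihood rather than genuine information.

## 5. Weighted inference

Associations are bivariate regressions fit by (weighted) least squares with
HC1 heteroskedasticity-robust standard errors:

* **Linear probability model** (`kind="lpm"`): a 0/1 outcome indicator on a
  0/1 exposure indicator — the slope is a difference in proportions.
* **Standardized slope** (`kind="standardized"`): both variables mapped to
  their numeric scores and standardized, so the unweighted slope is the
  Pearson correlation.

Cohort-vs-reference differences are tested with
`Z = (b_a - b_b) / sqrt(se_a^2 + se_b^2)`; the variances add because the two
samples are independent. **Bias reduction** for an association is
`1 - |b_weighted - b_reference| / |b_unweighted - b_reference|`, and is only
reported as *defined* when the unweighted bias is both materially nonzero
(`|b_unweighted - b_reference| > 1e-3`) and statistically unambiguous
(`|Z| > 4`); both thresholds were fixed a priori. Without such a rule,
near-zero denominators make the ratio meaningless noise.

## 6. Diagnostics

* **Kish effective sample size** `(sum w)^2 / sum w^2`, reported as a
  fraction of the cohort; it equals `n` exactly when weights are equal.
* **Regression-specific ESS** `n * (se_unweighted / se_weighted)^2` per
  association — the honest cost of weighting for that particular estimate,
  typically far below the Kish figure for exposures concentrated where
  weights are extreme.
* **Leave-one-out robustness.** For each association, all design columns
  touching either of its variables are removed, the penalized probit is
  re-cross-validated, and the bias reduction is recomputed. If correction
  survives, it does not hinge on the model containing the exact variables
  under analysis — selection on the remaining traits carries the needed
  information.

## 7. Collider scenarios

A linear-Gaussian toy model isolates why covariate adjustment cannot replace
weighting. `X -> Y` with slope `b`, optional common cause `U`, and a
selection index `S* = a_x X + a_y Y + a_u U + noise`; units with `S*` above
a threshold (set to hit a target selection rate) are observed. Because
`(X, Y, S*)` is jointly Gaussian, the selected-sample slope has an exact
oracle: conditional on `S* = s` the mean of `(X, Y)` is linear in `s` and the
covariance constant, so integrating over the truncated density of `S*` by
one-dimensional quadrature yields the exact selected moments and slope.
Presets cover no selection, selection on the exposure only (ignorable for
the slope), on the outcome, on both, on a common cause, and two independent
causes of selection (spurious association from a true slope of zero). On the
selected sample, regression-adjusting for a variable that drives selection
leaves the bias intact (or creates it, in the pure common-cause case it is
instead valid), while weighting by the true selection probability removes
it.

## 8. Numerical and scale choices

* Default eligible population 500,000 with a ~5.5% volunteer rate and a 5%
  × 95% reference sample: large enough that association standard errors are
  small relative to the injected biases, small enough for a laptop-scale
  run (a few minutes, single core).
* 14 penalty points down to `1e-4 * lambda_max`: the CV optimum for the
  default study sits in the interior of this grid; a shorter or shallower
  grid risks truncating the path at the boundary.
* 5 CV folds balance fit stability against runtime at cohort+reference
  sizes around 40,000 rows.
* Penalized-probit tolerances (KKT 1e-6, max 2000 FISTA iterations per
  working-set pass) were chosen so that unpenalized fits agree with an
  independent Newton MLE to 1e-4 relative error.
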