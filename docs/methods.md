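# Methods

`neopim` estimates population-intervention attributable risks for neonatal
mortality from survey microdata of recent live births. This note records the
statistical model, the estimators, the synthetic-data generator used to
validate them, and the design choices made where the design was genuinely
open.

## The estimand

For a binary outcome Y (death within the first 28 days of life) and a binary
exposure A_j (1 = exposed: lacked a service, or carries a high-risk birth
history), the target parameter is

    phi_j = E[Y_0^j] − E[Y],

the change in the population mean outcome had everyone been unexposed to
A_j, with all *other* exposures left as they are. It is the sign-reversed
analogue of the classical population attributable risk: a harmful exposure
yields a negative phi_j (deaths per 1000 that could have been averted).
Because the parameter intervenes on one exposure at a time, each exposure in
a set gets its own propensity model while all exposures share one outcome
model.

Estimation is marginal over a fixed *exposure set*. Three pre-registered
sets reflect pairs too entangled to analyse jointly: set A = {IDELIV, ANC4,
FP_UNMET, SHORT_INTERVAL, FIRST_PREG}, set B swaps the birth-interval
variables for TWO_PLUS_5Y, set C swaps in PREV_NNM. Lack of skilled
attendance (SBA) is a swap-in replacement for non-institutional delivery
(IDELIV) in sensitivity runs; the two never co-occur in one set.

## Estimators

Four estimators are reported per exposure:

* **naive** — 1000·p·(r0 − r1) from the exposed prevalence p and the two
  category rates; no adjustment, no standard error. This is the identity
  "unexposed-category rate minus overall rate" written in closed form.
* **gcomp** — plug-in standardisation through the fitted outcome model
  Q(A, W): phi = E_n[Q(A with A_j:=0, W)] − E_n[Y]. The standard error is a
  nonparametric bootstrap (default 500 resamples; clusters are resampled
  when design identifiers are present; the CV-chosen learner is refit per
  resample without re-running the CV selection).
* **ipw** — stabilised (Hájek) inverse-probability weighting through the
  propensity g_j(0 | co-exposures, W). Its standard error treats the fitted
  propensity as known and is diagnostic-grade only.
* **tmle** — targeted maximum likelihood. The initial Q fit is updated by a
  one-dimensional weighted logistic fluctuation of Y on the clever covariate
  H = 1(A_j=0)/g_j with offset logit(Q), no intercept. One step solves the
  efficient influence-curve (EIC) equation for this parameter exactly; the
  run asserts |weighted mean IC| < 1e-8 and fails loudly otherwise. The
  influence curve

      IC_i = H_i (Y_i − Q*(A_i,W_i)) + Q*(A_j:=0, W_i) − Ê[Y_0] − (Y_i − Ȳ)

  gives SE = sqrt(Var_w(IC)/n), a two-sided normal test and 95% intervals.

The fluctuation is solved by a damped Newton iteration on the concave
one-parameter likelihood rather than a generic GLM call: it is two lines of
numerics, cannot be silently mis-converged, and makes the EIC assertion
hold to solver precision.

### Nuisance learners

Two learner families are provided, matching the toolchain of the analysis:

* weighted main-effects **logistic regression** (statsmodels GLM). Constant
  outcomes return a flagged constant predictor; separation or
  non-convergence (detected by divergence of the coefficient norm past 30)
  falls back to a ridge-stabilised Newton fit with a fixed L2 penalty of
  1e-6 on the slopes, with a logged flag.
* weighted **recursive partitioning**: a CART-style probability tree grown
  by greedy weighted-Gini splits. Stopping rules: node weight < `min_split`
  (default 20, in mean-1 weight units, i.e. roughly rows), child weight <
  `min_leaf` (7), depth = `max_depth` (30), or best *relative* impurity
  decrease ≤ `complexity_threshold` (0.01). Leaves predict the weighted
  mean of Y. Ties in the split search break toward the lower column index,
  then the lower threshold, so fits are fully deterministic. These defaults
  mirror conventional recursive-partitioning practice.

A **discrete super learner** selects among candidate learners by v-fold
cross-validated weighted Bernoulli log-loss (held-out predictions clipped to
[1e-6, 1−1e-6] so degenerate leaves keep the risk finite) and refits the
winner on all data; ties break toward the first candidate listed. v is not
dictated by the method and defaults to 10. The selector — not a convex
ensemble — is implemented because selection of the single best candidate is
what the analysis toolchain does. The default pipeline configuration uses
logistic regression for the g models and recursive partitioning for the Q
model (the models the analysis states it used); passing both candidates for
either role engages the CV selection.

### Weights, truncation, variance

* Sampling weights enter every stage — g fits, Q fits, fluctuation,
  empirical means, IC variance — as *relative* weights, so every estimate
  and SE is invariant to the weight scale. The source analysis states only
  that weights entered the intervention model; using them uniformly is the
  coherent reading, and each stage can be switched off (`use_weights`).
* Propensities are truncated below at `g_min` (default 0.01, conventional);
  truncation is counted and reported, never silent. A positivity report
  gives per-exposure raw min/max propensities, truncation counts, and a
  flag for fully determined covariate strata (raw predictions within 1e-6
  of 0 or 1). An exposure that is constant in the data raises an error
  naming it.
* Default standard errors use the i.i.d. per-observation IC variance,
  matching the per-observation description of the methodology; a
  cluster-summed IC variant is available (`variance="cluster"`). Whether
  the original analysis accounted for the survey's cluster design is not
  stated, so neither option is asserted as "the" published choice.
* No multiple-testing adjustment is applied across exposures (per-exposure
  unadjusted p-values, as published).

## Synthetic data generator

The generator emulates the survey the analysis draws on: one row per
mother's most recent live birth within the recall window.

* **Covariates** are drawn independently at the published sample margins
  (region, residence, maternal age and education, household-head sex,
  wealth quintile, child sex, recalled child size).
* **Exposures** are each Bernoulli in a logistic index of a small fixed
  confounder set (rural residence, education, wealth), with the intercept
  solved numerically (bracketed root-find) so the marginal prevalence hits
  the published value; an unreachable target raises an error reporting the
  achievable range. Exposures are conditionally *independent given the
  covariates*: their mutual correlations arise through the shared
  confounders only, so the one-at-a-time parameter remains identifiable
  whichever subset of co-exposures an analysis set adjusts for. The one
  structural exception is the schema's hard constraint that a preceding
  birth interval exists only for non-first pregnancies: SHORT_INTERVAL is
  drawn among non-first rows (its marginal prevalence still matches), which
  is why SHORT_INTERVAL and FIRST_PREG are analysed in the same set.
  TWO_PLUS_5Y counts the index birth among the recent pregnancy outcomes
  (so a first pregnancy can reach two outcomes only through multiples), and
  PREV_NNM is drawn from the covariates alone; the generator trades full
  birth-history coherence for this conditional independence, and simulating
  longitudinal histories is out of scope.
* **Outcome**: Y ~ Bernoulli(expit(beta_0 + beta·A + gamma·W)). The default
  coefficients were calibrated once, by a nine-equation root-find on a
  fixed large covariate draw, so that the generator's true overall death
  rate is 18.5 per 1000 and the true phi_j of the eight exposures equal the
  adjusted estimates published for them (−1.3, −1.6, −2.1, −1.2, −1.3,
  −3.9, −3.2, −0.2 per 1000). The calibration routine ships in the package
  (`calibrate_outcome_betas`) and a test checks the frozen defaults
  reproduce the targets on a fresh draw.
* **Truth**: for each generated dataset the *exact finite-population*
  counterfactual is reported: phi_j = mean over rows of expit with A_j
  forced to 0 minus the mean with exposures as drawn. Co-exposures stay at
  their generated values, mirroring the one-exposure-at-a-time parameter.
  Given the rows there is no Monte Carlo error, which makes recovery tests
  exact up to estimator error. The truth is defined over the generated rows
  (a sample-average estimand), not a super-population integral.
* **Design**: strata are region × residence; each stratum holds a frame of
  enumeration areas (default 60, sizes uniform on 80–320) of which 30% are
  sampled systematically proportional-to-size; households within a sampled
  area are taken at a per-stratum fraction (default 0.25 everywhere).
  Records are allocated to sampled areas proportional to area size, and the
  weight is the inverse overall inclusion probability, normalised to mean
  1. With equal within-fractions the default weights vary by cluster
  (roughly four-fold) but are non-informative for the effects — deliberately
  so, because the truth is the sample-average estimand; unequal per-stratum
  fractions (an urban oversample, say) are one config key away and produce
  inversely proportional weights. The weight scale itself is a convention
  and all estimators are invariant to it.
* **Missingness** can be injected per field at stated rates (never in the
  outcome or design fields) to exercise complete-case accounting; it is
  missing-completely-at-random only.
* A single seed drives each call; every stage draws from its own
  deterministically derived substream, so adding a stage never perturbs
  earlier draws, and identical (config, n, seed) yields byte-identical
  output.

What passing tests on this generator do *not* show about real survey data:
real exposures are entangled beyond shared socio-demographic confounding
(e.g. skilled attendance and facility delivery are near-deterministically
linked), real weights are informative, outcomes cluster within mothers and
communities beyond what covariates capture, and missingness is not random.
The generator validates the estimation machinery, not those features.

## Validation studies bundled with the test suite

* **Oracle equivalence**: on discrete instances (≤3 binary covariates) with
  saturated stratification fits, TMLE equals exhaustive-stratification
  G-computation to 1e-8 with fluctuation coefficient ≈ 0.
* **EIC equation**: every successful TMLE run has |weighted mean IC| < 1e-8
  (asserted inside the estimator).
* **Parameter recovery**: 100 replicates at n = 10,000 with both nuisances
  correctly specified recover the calibrated true phi for IDELIV
  (−1.3/1000) and FIRST_PREG (−3.9/1000) to within 0.4/1000 on average.
* **Type-I error**: under a null generator (all exposure coefficients 0)
  the 5%-level z-test rejects in 3–7% of 500 replicates at n = 4000.
* **Coverage**: nominal 95% IC intervals cover the true phi in 90–97% of
  300 replicates at n = 10,000.
* **Double robustness**: on a strongly confounded single-confounder
  generator at n = 100,000, TMLE errs by far less than the 10%-of-phi
  margin with exactly one nuisance correct, while G-computation fails with
  the misspecified outcome model and IPW fails with the misspecified
  propensity.

Simulation sizes (replicate counts, n per replicate) are the package's
choices for a thorough-but-routine validation run; the recovery studies use
logistic learners for both nuisances because those are the generator's true
functional forms ("both-correct" specification).

## Numerical choices and degenerate inputs

* Q predictions are clipped to [1e-6, 1−1e-6] before the logit offset
  (partition leaves can be exactly 0/1).
* The naive estimator uses the algebraic form p·(r0 − r1), exact at r0 = r1.
* Empty exposure categories report NaN rates, never 0.
* Complete-case filtering drops a row only for missingness in a field the
  analysis actually uses, and always reports the count; the estimators do
  not model missingness.
* An unsplittable partition root returns the weighted-mean predictor;
  `complexity_threshold = 1` prunes every split by construction.
* Reported tables round per-1000 values to one decimal at the reporting
  layer only; machine-readable outputs keep full precision.

## Known limitations

* The IPW standard error ignores propensity estimation error.
* The gcomp bootstrap refits the selected learner but not the CV selection.
* IC-based inference assumes n is large relative to the number of events;
  with very rare exposures (PREV_NNM at 0.9%) finite-sample bias of the
  logistic nuisances is visible at n ≈ 10,000, and estimates for such
  exposures should be read with their (wide) intervals.
* The package consumes a documented flat CSV schema, not raw survey recode
  files, and expects `fp_need_unmet` as a precomputed binary.
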