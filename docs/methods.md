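# Methods

`synthrisk` implements a two-layer approach to forecasting the population
(regional) risk of suicide from administrative-style health records:

1. an **individual-level, sex-specific logistic model** developed on a
   case-control sample (all suicide deaths plus a small yearly fraction of
   living controls), and
2. a **model-based synthetic estimator** that applies the fitted
   coefficients to region-level covariate aggregates, yielding a regional
   suicide-risk estimate per year and sex.

A synthetic-cohort generator provides populations with the statistical
structure this method assumes, so the whole pipeline can be exercised and
validated end to end without access to restricted registry data.

## 1. Individual-level model

For person *i* with predictor vector `x_i` (lookback-window indicators,
continuous covariates, deprivation-quintile dummies), the outcome
`y_i ∈ {0,1}` (death by suicide in the year) follows

    logit P(y_i = 1) = β0 + βᵀ x_i .

**Case-control design and the intercept.**  Because suicide is rare
(~10⁻⁴/year), the model is fitted on all cases plus a fraction
`f` (default 0.01) of living person-years.  Slopes estimated under this
design are consistent for their population values; the intercept is
inflated by `ln(1/f)`.  Before any population-scale prediction the
intercept is therefore shifted by `ln f`
(`synthrisk.estimation.intercept_correction`); with `f = 0.01` the shift
is −ln 100 ≈ −4.6052.  The correction is applied by default when a
`SyntheticEstimator` is constructed and is recorded in the model metadata
and run logs — it is the single assumption that reconciles case-control
fitting with per-100,000 population estimates.

**Predictors.**  Lookback-window indicators are 1 iff at least one event of
the type occurred in the half-open interval `(index_date − w, index_date]`,
with `w ∈ {3, 6, 12, 24, 36, 48, 60}` months.  The index date is the death
date for cases and a uniformly random date within the sampling year for
controls.  Dates are fractional calendar years; a window of `w` months is
`w/12` years.  Deprivation scores are grouped into quintiles against a
population reference distribution (group 1 = most privileged).  One
predictor in the packaged female table, "Duration of hospitalisation for
Physical health reasons_6m", is days-of-stay in the source; the generator
models it as an occurrence indicator (its coefficient, 0.007, makes the
numerical difference negligible at regional scale).

**Model development.**  Candidates are screened by L1-penalised (LASSO)
logistic regression with the penalty chosen by stratified cross-validated
deviance (columns standardised internally, coefficients reported on the
original scale); survivors with pairwise |Pearson r| ≥ 0.60 are reduced to
one member per pair by an explicit caller-supplied priority list (the
programmatic stand-in for subject-matter judgment; for binary pairs Pearson
r is the phi coefficient).  The final model is pruned by backward
elimination on AIC (BIC is computed and reported alongside; the criterion
is selectable), removing at each step the predictor whose removal most
decreases the criterion and stopping when no removal improves it; the full
trace is stored and is non-increasing by construction.  Binary predictors
with an outcome-pure 2×2 cell (quasi-separation: their ML coefficient
diverges) are dropped from the candidate set with a warning before
fitting; true perfect separation inside a fit is a hard error naming the
predictor.  P-values are Wald tests and labelled as such.

**Diagnostics.**  Discrimination is the C statistic (concordance
probability, ties ½) with a DeLong structural-component CI by default
(bootstrap optional); calibration is the Brier score plus a 10-bin
risk-ranked calibration table (stable sort; ties keep input order; bins
are never merged, so counts always sum to n).

## 2. Synthetic estimation

For region *r*, year *t*, sex *s*:

1. every model predictor is aggregated over the region's full panel
   population — the within-region **proportion** for indicators and
   dummies, the within-region **mean** for continuous predictors.  Window
   predictors are evaluated for everyone at a common reference date,
   December 31 of the year, since regionwide aggregates need a common
   clock.  Aggregates are computed per region-year (configurable in
   principle; the per-year choice lets covariate drift move the forecast);
2. the regional logit is `η_rts = β0 + βᵀ x̄_rts`, converted to a
   probability and a rate per 100,000.

The aggregation population is the full simulated population of the
region-year, never the case-control sample (which is outcome-enriched).

**Jensen gap.**  Evaluating the inverse-logit at mean covariates instead of
averaging individual probabilities is the method's intrinsic
approximation: because the inverse-logit is convex at small risks,
`invlogit(βᵀx̄) ≤ mean(invlogit(βᵀx))`, so the synthetic estimate
*underestimates* the regional mean risk, increasingly so the larger the
slopes and the more heterogeneous (and correlated) the predictors.
`jensen_gap_diagnostic` reports both quantities per region.  In the default
synthetic world — where predictors share a single latent severity factor
and several coefficients exceed 1 — the provincial synthetic estimate runs
a factor ~2–3 below the observed rate.  This does not affect regional
*ranking* (the estimator is monotone in the aggregates), which is why
top-k identification is the headline validation metric here, while the
absolute per-100k agreement reported for the real registry data is not
reproducible in a world this strongly latent-factor-correlated.

## 3. Validation

Predicted and observed regional rates are compared per year and sex with
MAE, RMSE, and the top-k overlap `|top-k(pred) ∩ top-k(obs)|/k` (default
k = 5; ties broken by rate descending then region id, for
reproducibility).  MAE/RMSE are computed on rates per 1,000 population by
default — the magnitudes printed in the published evaluation are
consistent with that unit, not with per-100k differences — and the unit is
always carried in the report header.  Observed rates use the simulated
region-year panel population as denominator (stated in each report).
Subgroup validation restricts both the observed rate and the synthetic
aggregation to age bands (or any disjoint partition); empty subgroups are
flagged, not fatal.

## 4. The synthetic world (generator defaults)

The generator's defaults state the world the method assumes:

- **Scale and structure:** 18 health regions with population shares from
  0.25 (one metropolitan region) down to 0.015 (small northern regions);
  years 2002–2019 with 2002–2010 for development and 2011–2019 for
  validation; male fraction 0.49; ages at entry from a normal(45, 19)
  clipped to [15, 95] (the target population is ages ≥ 15).
- **Outcome schedule:** male suicide rate declining linearly from 27 to
  20 per 100,000 over 2002–2019; female stable at 6.5 per 100,000.  The
  per-sex-year intercept is calibrated by bisection so that the simulated
  marginal rate matches the schedule exactly in expectation; if an
  explicit intercept is supplied it is used unchanged (that is the
  parameter-recovery configuration).
- **True coefficients:** the packaged male (20-predictor) and female
  (22-predictor) coefficient tables themselves.  The simulated outcome is
  drawn from the published model, so fitted models and the packaged
  fixtures speak the same predictor vocabulary.
- **Event histories:** each of the ~24 base event types occurs per
  person-year with probability `invlogit(a_e + b_e z)`, where `z` is a
  single latent severity factor per person, `z ~ N(μ_region, 1)`.
  Mental-health service contacts and psychiatric diagnoses have strong
  loadings (b ≈ 0.8–1.3), somatic diagnoses weak ones (b ≈ 0.1–0.5).  The
  shared factor induces the between-predictor correlations that make the
  |r| ≥ 0.60 filter meaningful.  Five burn-in years of events precede the
  first study year so 60-month windows are well defined from the start.
- **Regional heterogeneity is covariate-mediated:** regions shift the
  severity mean (μ from −0.35 to +1.90), the rural fraction (0.02 to
  0.95), deprivation, and the regional budget covariate; the direct
  regional intercept offset defaults to zero.  This yields male regional
  rates spanning roughly 10–280 per 100,000 (female ~2–75), the "strong
  between-region variation" regime, while remaining explicable by an
  individual model without region terms — the property synthetic
  estimation relies on.
- **Sampling and missingness:** control fraction 0.01 per year, each
  person selectable as a control once (Bernoulli per eligible person-year,
  so the per-row inclusion probability is exactly `f`); per-variable
  missingness between 0.87% and 4.12%, resolved by complete-case analysis
  by default (imputation available: mean for continuous, mode for binary).
- **Determinism:** every stochastic operation is driven by a single
  integer seed through `numpy.random.default_rng`; identical configuration
  and seed reproduce byte-identical outputs.

**What the generator does not emulate.**  Death from other causes (persons
persist unless they are cases), migration between regions, ageing-in of
new cohorts, seasonality, event-type-specific temporal trends, true
duration/count intensities of service use, and any geographic adjacency.
Controls sampled in year *t* are not excluded from becoming cases later
(the generator's outcome draw makes the overlap negligible at realistic
rates).  A green end-to-end test therefore establishes that the pipeline
recovers a known generating model and ranks regions correctly under the
stated structure — not that it reproduces registry-data performance.

## 5. Numerical choices and edge cases

- Intercept calibration: Brent root-finding on the mean predicted
  probability, tolerance 10⁻¹²; a zero target rate maps to −∞ (no events).
- Window boundary: half-open `(d − w, d]`; an event exactly at the index
  date counts.  Event dates are continuous, so boundary ties have
  probability zero.
- Quantile groups: reference cut points at the `k/n_groups` quantiles;
  scores below the reference minimum clamp to group 1; "quintile" (5
  groups) is the default against the published 5-level tables, with
  `n_groups` configurable.
- Correlation filter: constant columns have undefined correlation — they
  are reported separately and retained, never a crash.
- Calibration bins with heavily tied predictions: the stable sort keeps
  input order, bins stay near-equal in size and may share a predicted
  value; they are never merged.
- Coefficient tables: ASCII minus enforced on ingest (typographic minus
  signs normalised); displayed odds ratios are `exp(β)` rounded to 2
  decimals and validated against the stored coefficient on read; file
  writes are atomic (write-then-rename).
- Seeds derived for sub-stages stay below 2³¹.

## 6. Design choices where the procedure was open

- AIC is the default selection criterion with BIC reported, since the two
  are invoked jointly without a tie rule in the source procedure.
- The correlation-filter retention order is an explicit argument; the
  pipeline's default priority is the sex's true-model predictors first.
- MAE/RMSE unit per 1,000 (see §3), configurable to per 100k.
- Top-k ties: rate descending, then region id — any fixed rule works;
  this one is reproducible.
- The packaged fixture tables are loaded, never refit: three female-table
  predictors have p > .05, so no purely criterion-driven stopping rule
  would reproduce them; refitting in the synthetic world is a separate,
  explicitly labelled path.

## 7. Known limitations

- The Jensen gap biases synthetic levels downward in strongly correlated
  worlds (§2); rankings are unaffected.
- Female regional forecasts at desk scale (≤ 500k persons) are dominated
  by observed-rate noise — a region-year often has 0–3 female cases — so
  female top-5 overlap is reported but not a stable benchmark at this
  scale; at registry scale (millions of person-years) the same pipeline
  would not have this limitation.
- Backward selection refits the model once per candidate per step;
  with very wide candidate sets (≫ 30) a score-test screen would be
  cheaper.  At the pipeline's candidate-set sizes (≈ 20) this is
  irrelevant.
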