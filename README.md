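# synthrisk

Model-based **synthetic estimation of the population risk of suicide** at
the health-region level, built from individual-level case-control logistic
models on administrative-style health records.

Suicide-prevention planning needs forecasts of *regional* risk — which
health regions will carry the highest suicide rates next year — not
individual risk scores.  `synthrisk` implements the two-stage approach
used for this problem in public-health surveillance, for epidemiologists
and health-services researchers who want to develop, validate, or stress
test such models:

1. **Individual model.**  A sex-specific logistic model
   `logit P(y=1) = β0 + βᵀx` is developed on a case-control sample: all
   suicide deaths over the development period plus a fraction *f*
   (default 1%) of living individuals per year.  Predictors are
   lookback-window indicators (e.g. hospitalisation for a suicide attempt
   in the past 60 months), continuous covariates (age, comorbidity score,
   regional mental-health budget) and deprivation quintiles.  Candidates
   are screened by cross-validated LASSO, a |r| ≥ 0.60 correlation
   filter, and backward selection on AIC/BIC; performance is assessed by
   the C statistic and the Brier score.
2. **Synthetic estimator.**  The fitted coefficients are applied to
   *region-level aggregates* `x̄_r` (proportions for indicators, means
   for continuous predictors):
   `η_r = β0 + ln f + βᵀx̄_r`, with `invlogit(η_r) × 10⁵` the regional
   rate per 100,000.  The `ln f` term corrects the case-control intercept
   to the population scale.  Regional forecasts are validated against
   observed rates by MAE, RMSE and top-k high-risk-region overlap.

The package ships the published sex-specific coefficient tables
(20 predictors for males, 22 for females, development period 2002–2010)
as ready-to-use model fixtures, and a synthetic-cohort generator — an
18-region world with strong covariate-mediated regional rate variation —
so the whole pipeline runs end to end without restricted registry data.

## Worked example

```python
import synthrisk as sk

cfg = sk.default_config(n_persons=200_000, seed=1)      # the stated world
panel = sk.generate_population(cfg)                     # 18 regions, 2002-2019
train, valid = sk.split_train_validation(panel, 2011)
results = sk.fit_sex_models(train, seed=1)              # sample, screen, fit
print(results["male"].summary())
```

```
Case-control logistic model for suicide (male)
Training period: (2002, 2010), control sampling fraction f=0.01
n=7850 (203 cases), converged=True
C statistic 0.885 (95% CI 0.857-0.912); Brier 0.0198
AIC 1305.1  BIC 1381.7

predictor                                          coef      OR         p
Constant                                         -7.763       -  4.92e-25
Hospitalisation for Suicide attempt_60m           1.841    6.30  2.29e-24
Mood and anxiety disorders_12m                    0.397    1.49    0.0271
Mood and anxiety disorders_60m                    0.942    2.57  5.26e-05
Substance use disorders_60m                       0.658    1.93  0.000646
...
```

The intercept (−7.76) is on the case-control scale; odds ratios are
`exp(β)` (a prior suicide-attempt hospitalisation multiplies the odds by
6.3).  Converting to regional forecasts and validating on 2011–2019:

```python
models = {s: r.spec for s, r in results.items()}
report = sk.yearly_report(train, valid, models, k=5)
print(report.summary())
```

```
Regional suicide-risk forecast evaluation (MAE/RMSE unit: per_1000; top-5 overlap)
denominator: simulated region-year panel population
     period  year    sex      mae     rmse  top_k_overlap
...
 validation  2011   male 0.318215 0.520046            0.8
 validation  2012   male 0.307809 0.503137            0.6
 validation  2013   male 0.360456 0.492375            0.6
 validation  2014   male 0.317767 0.556410            0.8
...
```

A male top-5 overlap of 0.8 means 4 of the 5 observed highest-risk
regions that year were also the 5 highest predicted — the operative
question for allocating prevention resources.  MAE/RMSE are absolute
regional forecast errors on rates per 1,000 population.

The published coefficient tables can be applied directly, with no
refitting:

```python
male = sk.load_fixture_model("male")          # 20 predictors, Constant -4.85
est  = sk.SyntheticEstimator(male)            # applies the ln f correction
regional = est.predict_panel(panel, years=[2019], sex="male")
```

A `synthrisk` command-line interface wraps the same stages
(`simulate`, `features`, `fit`, `synthesize`, `validate`, `report`); every
run logs its seed, config hash and intercept-correction status, and all
file writes are atomic.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at reduced scale: it simulates
the default world (n = 200,000), draws the 2002–2010 case-control sample,
fits both sex-specific models, converts them into intercept-corrected
synthetic estimators, and evaluates the 2011–2019 regional forecasts
(MAE, RMSE, top-5 overlap per year and sex), writing the evaluation
tables next to the JSON manifest at `--out`.

## Layout

- `src/synthrisk/cohort.py` — synthetic population generator, case-control
  sampling, train/validation split
- `src/synthrisk/features.py` — lookback-window indicators, quantile
  groups, feature matrices, missing-data handling
- `src/synthrisk/model.py`, `metrics.py` — screening, logistic
  model/results objects, C statistic, Brier, calibration
- `src/synthrisk/estimation.py` — regional aggregation, intercept
  correction, synthetic prediction, Jensen-gap diagnostic
- `src/synthrisk/evaluation.py` — MAE/RMSE/top-k reports, subgroup
  validation
- `src/synthrisk/io.py`, `cli.py` — coefficient-table format, fixtures,
  run configs, command-line stages
- `docs/methods.md` — model assumptions, generator design, numerical
  choices, limitations
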