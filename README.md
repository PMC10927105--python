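# sitesel

Clinical-trial **site selection** by predicting patient enrollment.

Slow or failed recruitment is a major disruptor of clinical-trial
timelines, and sponsors rank candidate research sites (healthcare
organizations, HCOs) largely by gut feel and feasibility questionnaires.
`sitesel` implements a data-driven alternative: it predicts the number of
patients a site will enroll in a study from two kinds of covariates —

* **recruitment history** (per-site medians/EWMAs of past enrollment,
  within-study percentile ranks, and enrollment volume over a five-year
  window indexed on the site open date), and
* **real-world data (RWD)** — insurance-claims aggregates characterizing a
  site's clinical practice for the indication: relevant patients, treated
  patients, visits, physicians, specialists, referral flows, plus
  publication and trial-participation counts —

and evaluates how well the resulting *site ranking* identifies the
top/bottom recruiting sites.

## Model

Enrollment counts are modeled as Poisson with the enrollment duration as
exposure:

```
y_ij ~ Poisson(E_ij · exp(η_ij)),     η_ij = f(x_ij)
```

where `y_ij` is the number of patients site `i` enrolled in study `j`,
`E_ij` the enrollment-months, and `f` is either a linear predictor
(Poisson GLM with log-exposure offset) or a tree ensemble (random forest
on rates with exposure weights; gradient boosting with Poisson deviance
and log-exposure base margin). Two industry baselines are included: the
train-set **median** enrollment, and the per-site **historical median**.
Models are compared on MAE, RMSE, Spearman rank correlation, R², and the
AUC of identifying the top-30% / bottom-30% recruiting sites from the
predicted counts. Covariate importance uses exact per-row additive
(Shapley) attributions on the log-rate scale; covariates with mean |SHAP|
below 0.005 are dropped and the model refit.

Because real claims and enrollment databases are proprietary, the package
ships a **synthetic data generator** that emulates their schemas and
statistical structure (gamma-distributed site-size covariates, Poisson
counts with exposure, multi-study site histories, cross-HCO patient
journeys that induce referrals) and records its ground truth so that every
stage is testable by parameter recovery.

## Worked example

```python
from sitesel.pipeline import PipelineConfig, run
from sitesel.synthetic_data import GeneratorConfig

config = PipelineConfig(
    generator=GeneratorConfig(n_sites=100, n_studies=15, seed=3),
    families=("median_baseline", "site_baseline", "linear_poisson",
              "random_forest", "gradient_boosting"),
    n_trials=0,   # skip hyperparameter search for a quick run
    seed=3,
)
report = run(config, "out/demo")
print(report.test_frame().round(2))
```

prints (test-set metrics, one row per model):

```
                   Test R2  Test Spearman correlation coefficient  Test RMSE  Test MAE  Test Top 30% AUC  Test Bottom 30% AUC
median_baseline      -0.04                                    NaN      11.59      4.75              0.50                 0.50
site_baseline         0.29                                   0.43       9.54      4.27              0.68                 0.68
linear_poisson        0.93                                   0.84       2.90      1.78              0.93                 0.89
random_forest         0.81                                   0.86       5.01      2.28              0.94                 0.90
gradient_boosting     0.80                                   0.85       5.11      2.30              0.94                 0.90
```

The constant median baseline has no ranking power (Spearman undefined,
AUC exactly 0.50); the site-history baseline ranks moderately; the
covariate models rank far better, and their top/bottom-30% AUCs show they
reliably identify the best and worst recruiting sites. The run directory
additionally contains `features.csv`, `clip_bounds.json`, per-model
importances and SHAP dependence curves, and a `manifest.json` of all
seeds; re-running the same config reproduces every output byte for byte.

A command-line interface wraps the same stages:

```bash
sitesel synth --config generator.yaml --out data/       # synthetic tables
sitesel run   --config pipeline.yaml  --out out/run1/   # full pipeline
```

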