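# Methods

## The prediction problem

The unit of analysis is the *(study, site)* pair: one row per participation
of a research site (healthcare organization, HCO) in a clinical study. The
target `y` is the number of patients the site enrolled in that study; the
exposure `E` is the enrollment duration in months (site open date to last
subject enrolled). Counts are modeled as Poisson with mean `E · exp(η)`,
so models learn a log *rate* and predictions scale with how long a site
recruits. Two covariate families feed `η`:

* **study-site level** (change per study): site open year, enrollment
  months, and five-year history summaries — median/EWMA of patients per
  month, median/EWMA of the site's within-study percentile rank, and
  median/EWMA/sum of enrolled patients. The window is indexed on the site
  open date and is half-open `[open − 5y, open)`, so the current study and
  anything opening on or after it is excluded (no future leakage).
* **site level** (treated as static): claims-derived aggregates over the
  cohort observation window — unique relevant claims, patients, treated
  patients, visits, visits per patient, physicians, treating physicians,
  specialists, patient/site referral-flow differences — plus the maximum
  indication-specific publication count across the site's physicians and
  ongoing / sponsor trial counts and a past-trial-experience flag.
  Treating these as time-constant assumes the site's clinical practice
  varies slowly relative to the study horizon.

## Cohort and referral construction

A cohort definition (half-open observation window, age range, diagnosis /
drug / procedure code lists, specialist types) approximates a trial's
eligible population in claims. A claim is *relevant* when its service date
falls in the window, the patient age is in range, and its diagnosis codes
intersect the cohort's; a patient is *treated* when any retained claim
carries a cohort drug or procedure code. Referrals are not recorded in
claims, so they are derived from patient journeys: two consecutive
qualifying encounters of one patient at distinct HCOs within `gap_days`
(default 90, a conventional care-transition window, configurable) count as
a referral from the earlier to the later HCO. Incoming minus outgoing
events give the patient flow difference; distinct senders minus distinct
receivers give the site flow difference.

## Preprocessing

Covariates are right-skewed (gamma-like), so outliers are clipped on the
right only: per covariate, the 97.5th percentile (linear interpolation
between order statistics) of the **training rows** is the cap applied to
all rows; bounds are stored for reuse at prediction time. The lower end is
left untouched — the natural lower reference is the sample minimum, and
flow differences are legitimately negative. Missing values (sites without
claims coverage, empty history windows) are imputed with 0 after clipping,
with per-cell imputation flags retained. The EWMA is time-aware,
`w = 0.5^(age / half_life)` with a 2-year default half life — the source
conventions name an EWMA but no decay, and an age-based decay is robust to
irregular study spacing. Within-study rank is normalized to (0, 1] with
average ranks for ties (1 = top enroller), making ranks comparable across
studies of different sizes.

## Models

* **Median baseline** — the train-set median count for every row; by
  construction it has no ranking information (its top/bottom-30% AUC is
  exactly 0.5 under the Mann–Whitney tie rule).
* **Site baseline** — the site's historical median count. Sites absent
  from training can optionally be scored from their own enrollment history
  with the current study left out, mirroring the industry practice of
  quoting a site's historical numbers; without a history table, unseen
  sites get the median of per-site training medians. Baselines predict raw
  counts and ignore exposure (a rate-based variant exists behind
  `use_exposure` but is off by default).
* **Linear Poisson GLM** — log-exposure offset; fitted by IRLS
  (statsmodels) on internally standardized covariates, with coefficients
  mapped back exactly (a pure reparametrization for numerical stability).
  Zero-variance covariates get coefficient 0; a rank-deficient design
  falls back to a tiny ridge penalty (1e-6) with a warning; non-converged
  fits raise.
* **Random forest** — forests have no native offset, so the Poisson mean
  structure is preserved approximately by regressing rates `y/E` with
  per-row weight `E` (Poisson split criterion) and predicting `rate · E`.
* **Gradient boosting** (xgboost, Poisson deviance) — log exposure enters
  as per-row base margin; prediction is computed as `E · exp(margin)`, so
  under `exposure_mode="offset"` predictions are *exactly* proportional to
  exposure. Defaults: 400 rounds, learning rate 0.05, depth 3,
  min_child_weight 10, subsample/colsample 0.8 — moderate settings for
  tabular count data of a few thousand rows.

`exposure_mode` is `offset`, `feature` (months as an ordinary covariate —
the recruitment period is itself predictive) or `both` (default for the
tree models; offset for the GLM).

Hyperparameters are tuned by uniform random search (default budget 128
trials) scored by the mean out-of-fold Spearman correlation over
site-level cross-validation folds — models are selected for their ability
to *rank* sites, not minimize squared error. The default gradient-boosting
search space (depth 2–8, learning rate log-uniform 0.01–0.3, 50–500
rounds, min_child_weight 1–10, subsample 0.5–1.0) is a stand-in
documented here; the originally used grid is not public.

## Evaluation

Data are split 80/20 at **site** level (every row of a site shares its
partition), so test metrics measure generalization to unseen sites; the
same site-level grouping builds the 5 cross-validation folds. Reported
metrics: MAE, RMSE, Spearman (undefined for constant predictions and
reported as missing), R² (reference only), and top/bottom-30% AUC: rows
are labeled by whether their actual count is among the `⌈0.3·n⌉` largest
(smallest), with boundary ties broken by site id, and the continuous
predicted count is the score — negated for the bottom direction, since
identifying the worst recruiters means ranking by *low* predicted
enrollment. The AUC uses the Mann–Whitney form with half credit for tied
score pairs. Model pairs are compared with a dependent t-test on per-row
absolute errors (two-sided; p undefined when differences have zero
variance).

## Covariate importance

Importance is the mean absolute per-row additive attribution on the
log-rate margin, computed on training rows: exact TreeSHAP (xgboost's
native contribution predictor) for gradient boosting, and the closed form
`β_j (x_j − x̄_j)` for the GLM (exact for a linear model). Attributions
plus the base value reconstruct each row's margin (to 1e-6 for trees,
1e-8 for the GLM). Covariates with importance below 0.005 (margin units)
are removed and the model refit; selection is monotone in the threshold.
Baselines and the random forest expose no additive attribution and raise.
Dependence curves export per-row (value, attribution) pairs for plotting.

## Synthetic data generator

The generator emulates the linked proprietary sources at realistic scale:

* **Sites.** Latent size factors `s_i ~ Gamma(2, 5)` (mean 10, strongly
  right-skewed, like hospital volumes).
* **Site covariates.** For each named covariate, a gamma draw (shape 4)
  whose mean scales with `s_i` — so covariates are skewed and mutually
  correlated, as claims aggregates are. Declared noise covariates are
  drawn independently of size and have no effect on enrollment.
* **Claims.** Each site receives its covariate-implied number of
  cohort-qualifying patients (ages in range, cohort diagnosis codes,
  1–4 visits; ~60% treated via drug/procedure codes; ~25% of visits carry
  a second claim line), plus ~30% non-qualifying patients (age or code
  violations) to exercise the cohort filter. A `referral_rate` fraction of
  patients (default 0.1) later visit a second, random HCO, creating the
  cross-HCO journeys the referral derivation consumes.
* **Enrollment.** Each of `n_studies` (default 20) samples ≥ 30% of the
  `n_sites` (default 200) sites; open dates are uniform over a 10-year
  span; exposure is a shifted exponential (mean 12 months, floor 1). The
  log rate is `η = intercept + Σ β_j z_j + γ z_a z_b` where `z` are
  z-scores of **log** covariates — an elasticity-style effect; z-scoring
  raw gamma draws would let single extreme sites dominate `exp(η)` and
  produce implausible thousand-patient rows. Defaults: intercept −1.3,
  β = 0.4 (patients), 0.2 (specialists), 0.15 (publications), 0.1
  (ongoing trials), interaction strength 0.3 on (patients, specialists).
  These yield a median of ~3 enrolled patients per row with a long right
  tail (95th percentile ≈ 20), the magnitude seen in per-site trial
  recruitment data. The ground truth (per-row `η`, the z design, all
  coefficients) is recorded for recovery tests.

What the generator does **not** emulate: real code vocabularies,
payer/adjudication semantics, temporal drift in site practice, study-level
effects (phase, eligibility-criteria strictness) and site–study matching
beyond random subsets. Passing tests therefore demonstrate the
correctness of the machinery and its behavior under the stated
generating process, not predictive performance on proprietary data.

## Problem sizes and numerics

Simulation studies in the test suite use deliberately moderate sizes:
coefficient recovery at ~1,000 rows over 50 replicates, model comparisons
at 200 sites over 20 replicates, distributional checks at 10,000 sites.
Determinism: every stage draws from independent seeded streams
(`SeedSequence`), tree learners run single-threaded with fixed seeds, and
a pipeline rerun reproduces outputs byte-identically. Degenerate inputs
are defined: empty history windows are missing (imputed 0), constant
predictions have undefined Spearman, single-class label sets make the AUC
undefined (error), zero-variance error differences make the paired-test p
undefined, and a single-site study has rank 1.0.

## Known limitations

* The referral rule (consecutive encounters within 90 days) is a declared
  convention; claims do not record referrals explicitly.
* The mean-|SHAP| of a *truly independent* noise covariate does not fall
  to zero in gradient boosting — it absorbs a small amount of overfit
  margin variance (≈0.01 at a few thousand rows, shrinking slowly with
  n), so a fixed absolute threshold such as 0.005 separates unused or
  redundant covariates from retained ones, not arbitrary noise from
  signal.
* Forest exposure handling (rate target + weights) preserves the Poisson
  mean structure only approximately.
* RWD covariates are static over the observation window; studies opening
  before claims coverage begins inherit this approximation.
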