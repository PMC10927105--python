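"""Baselines, Poisson learners and the random hyperparameter search."""

import numpy as np
import pandas as pd
import pytest

from sitesel.errors import ConfigError
from sitesel.models import (
    Choice,
    MedianBaseline,
    ModelSpec,
    PoissonBoosting,
    PoissonForest,
    PoissonRegression,
    SiteBaseline,
    make_estimator,
    tune,
)
from sitesel.synthetic_data import GeneratorConfig, covariate_level_frame


def frame_of(y, sites=None, months=None, **covs):
    n = len(y)
    data = {
        "study_id": [f"S{i}" for i in range(n)],
        "site_id": sites if sites is not None else [f"H{i}" for i in range(n)],
        "patients_enrolled": y,
        "enrollment_months": months if months is not None else np.ones(n),
    }
    data.update(covs)
    return pd.DataFrame(data)


class TestMedianBaseline:
    def test_odd_median(self):
        f = frame_of([1, 2, 9])
        model = MedianBaseline().fit(f, f["patients_enrolled"])
        assert model.predict(f).tolist() == [2, 2, 2]

    def test_even_median(self):
        f = frame_of([4, 6])
        model = MedianBaseline().fit(f, f["patients_enrolled"])
        assert model.predict(f).tolist() == [5, 5]

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            MedianBaseline().fit(frame_of([]), [])


class TestSiteBaseline:
    def test_per_site_median(self):
        f = frame_of([2, 8, 3], sites=["A", "A", "B"])
        model = SiteBaseline().fit(f, f["patients_enrolled"])
        pred = model.predict(frame_of([0, 0], sites=["A", "B"]))
        assert pred.tolist() == [5.0, 3.0]

    def test_unseen_site_gets_fallback(self):
        f = frame_of([2, 8, 3], sites=["A", "A", "B"])
        model = SiteBaseline().fit(f, f["patients_enrolled"])
        pred = model.predict(frame_of([0], sites=["Z"]))
        assert pred.tolist() == [4.0]  # median of per-site medians {5, 3}

    def test_single_row_sites_fallback_is_median_of_values(self):
        f = frame_of([1, 5, 9], sites=["A", "B", "C"])
        model = SiteBaseline().fit(f, f["patients_enrolled"])
        assert model.site_medians_ == {"A": 1.0, "B": 5.0, "C": 9.0}
        assert model.fallback_ == 5.0

    def test_history_enables_leave_study_out_for_unseen_site(self):
        f = frame_of([2, 8], sites=["A", "A"])
        history = pd.DataFrame(
            {"study_id": ["S1", "S2", "S3"], "site_id": ["Z", "Z", "Z"],
             "patients_enrolled": [10, 20, 30]}
        )
        model = SiteBaseline(history=history).fit(f, f["patients_enrolled"])
        pred = model.predict(
            pd.DataFrame({"study_id": ["S3"], "site_id": ["Z"],
                          "enrollment_months": [1.0], "patients_enrolled": [0]})
        )
        assert pred.tolist() == [15.0]  # median of the other studies {10, 20}


class TestBaselinesIgnoreCovariates:
    def test_permuting_covariates_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(0)
        f = frame_of(rng.integers(0, 9, 30), sites=list("ABCDEF") * 5,
                     x1=rng.normal(size=30), x2=rng.gamma(2, 2, 30))
        permuted = f.copy()
        permuted[["x1", "x2"]] = f[["x1", "x2"]].sample(
            frac=1, random_state=1).to_numpy()
        for cls in (MedianBaseline, SiteBaseline):
            model = cls().fit(f, f["patients_enrolled"])
            assert np.array_equal(model.predict(f), model.predict(permuted))


class TestPoissonRegression:
    def test_null_coefficients_near_zero(self):
        """beta = 0 in the generator: fitted coefficients are within 0.05."""
        cfg = GeneratorConfig(n_sites=160, n_studies=22, seed=31,
                              beta={"c1": 0.0, "c2": 0.0},
                              nonlinear_strength=0.0, noise_covariates=())
        frame, gt = covariate_level_frame(cfg)
        frame = frame.drop(columns=["c1", "c2"]).merge(
            gt.site_z.reset_index(), on="site_id")
        assert len(frame) >= 2000
        model = PoissonRegression(covariates=["c1", "c2"]).fit(
            frame, frame["patients_enrolled"])
        assert np.abs(model.coef_.to_numpy()).max() < 0.05

    def test_single_covariate_recovery(self):
        """beta = 0.5 at ~2000 rows: estimate in [0.4, 0.6]."""
        cfg = GeneratorConfig(n_sites=150, n_studies=20, seed=32,
                              beta={"c1": 0.5}, nonlinear_strength=0.0,
                              noise_covariates=())
        frame, gt = covariate_level_frame(cfg)
        frame = frame.drop(columns=["c1"]).merge(
            gt.site_z.reset_index(), on="site_id")
        model = PoissonRegression(covariates=["c1"]).fit(
            frame, frame["patients_enrolled"])
        assert 0.4 < model.coef_["c1"] < 0.6

    def test_doubling_exposure_doubles_prediction_exactly(self):
        rng = np.random.default_rng(2)
        f = frame_of(rng.integers(0, 10, 50), months=rng.uniform(1, 20, 50),
                     x1=rng.normal(size=50))
        model = PoissonRegression().fit(f, f["patients_enrolled"])
        doubled = f.assign(enrollment_months=2 * f["enrollment_months"])
        assert np.array_equal(model.predict(doubled), 2 * model.predict(f))

    def test_zero_variance_column_gets_zero_coefficient(self):
        rng = np.random.default_rng(3)
        f = frame_of(rng.integers(0, 10, 60), x1=rng.normal(size=60),
                     const=np.ones(60))
        model = PoissonRegression().fit(f, f["patients_enrolled"])
        assert model.coef_["const"] == 0.0

    def test_collinear_covariates_fall_back_to_ridge(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        f = frame_of(rng.integers(0, 10, 80), x1=x, x2=2 * x + 1)
        with pytest.warns(UserWarning, match="collinear"):
            model = PoissonRegression().fit(f, f["patients_enrolled"])
        assert model.used_ridge_

    def test_exposure_as_feature_mode(self):
        rng = np.random.default_rng(5)
        f = frame_of(rng.integers(0, 10, 50), months=rng.uniform(1, 20, 50),
                     x1=rng.normal(size=50))
        model = PoissonRegression(exposure_mode="feature").fit(
            f, f["patients_enrolled"])
        assert "enrollment_months" in model.coef_.index


class TestTreeModels:
    def test_constant_rate_target_recovered(self):
        """y = 2E for varying E: boosted predictions match to tiny deviance."""
        E = np.arange(1.0, 201.0) % 20 + 1
        f = frame_of((2 * E).astype(int), months=E,
                     x1=np.random.default_rng(0).normal(size=200))
        gb = PoissonBoosting(exposure_mode="offset", n_estimators=500,
                             learning_rate=0.3, subsample=1.0,
                             colsample_bytree=1.0, min_child_weight=1.0,
                             seed=0).fit(f, f["patients_enrolled"])
        mu = gb.predict(f)
        y = f["patients_enrolled"].to_numpy(float)
        deviance = 2 * np.mean(y * np.log(y / mu) - (y - mu))
        assert deviance < 1e-6

    def test_same_seed_identical_predictions(self):
        cfg = GeneratorConfig(n_sites=40, n_studies=6, seed=33)
        frame, _ = covariate_level_frame(cfg)
        y = frame["patients_enrolled"]
        for cls in (PoissonBoosting, PoissonForest):
            a = cls(seed=5).fit(frame, y).predict(frame)
            b = cls(seed=5).fit(frame, y).predict(frame)
            assert np.array_equal(a, b)

    def test_boosting_offset_mode_doubles_with_exposure(self):
        cfg = GeneratorConfig(n_sites=40, n_studies=6, seed=34)
        frame, _ = covariate_level_frame(cfg)
        gb = PoissonBoosting(exposure_mode="offset", n_estimators=50,
                             seed=0).fit(frame, frame["patients_enrolled"])
        doubled = frame.assign(enrollment_months=2 * frame["enrollment_months"])
        assert np.array_equal(gb.predict(doubled), 2 * gb.predict(frame))

    def test_forest_rate_structure(self):
        """Forest predictions scale with exposure under the rate target."""
        cfg = GeneratorConfig(n_sites=40, n_studies=6, seed=35)
        frame, _ = covariate_level_frame(cfg)
        rf = PoissonForest(exposure_mode="offset", n_estimators=50,
                           seed=0).fit(frame, frame["patients_enrolled"])
        doubled = frame.assign(enrollment_months=2 * frame["enrollment_months"])
        assert np.allclose(rf.predict(doubled), 2 * rf.predict(frame))


class TestSpecAndTune:
    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec(family="neural_net")

    def test_unknown_hyperparameter_rejected(self):
        spec = ModelSpec(family="gradient_boosting",
                         hyperparameters={"n_trees": 10})
        with pytest.raises(ConfigError, match="n_trees"):
            make_estimator(spec)

    def test_single_point_grid_returned(self):
        cfg = GeneratorConfig(n_sites=20, n_studies=4, seed=36)
        frame, _ = covariate_level_frame(cfg)
        grid = {"n_estimators": [30], "max_depth": [2]}
        spec = tune(frame, "gradient_boosting", grid=grid, n_trials=1,
                    cv_folds=3, seed=0)
        assert spec.hyperparameters == {"n_estimators": 30, "max_depth": 2}

    def test_degenerate_point_loses(self):
        """Zero trees cannot fit; the non-degenerate grid point wins."""
        cfg = GeneratorConfig(n_sites=30, n_studies=6, seed=37)
        frame, _ = covariate_level_frame(cfg)
        grid = {"n_estimators": Choice((0, 100))}
        spec = tune(frame, "gradient_boosting", grid=grid, n_trials=8,
                    cv_folds=3, seed=0)
        assert spec.hyperparameters["n_estimators"] == 100

    def test_same_seed_same_selection(self):
        cfg = GeneratorConfig(n_sites=30, n_studies=6, seed=38)
        frame, _ = covariate_level_frame(cfg)
        grid = {"max_depth": [2, 3, 4], "n_estimators": [20, 40]}
        a = tune(frame, "gradient_boosting", grid=grid, n_trials=4,
                 cv_folds=3, seed=9)
        b = tune(frame, "gradient_boosting", grid=grid, n_trials=4,
                 cv_folds=3, seed=9)
        assert a.hyperparameters == b.hyperparameters

    def test_n_trials_must_be_positive(self):
        with pytest.raises(ConfigError):
            tune(frame_of([1, 2, 3]), "gradient_boosting", n_trials=0)


def test_linear_recovery_bias_and_coverage():
    """Over 30 simulated datasets, the mean bias of each coefficient is
    within ±0.02 and ±1.96 SE intervals cover the truth 90-99% of the time."""
    beta = {"c1": 0.4, "c2": -0.2, "c3": 0.1, "c4": 0.0, "c5": 0.25}
    truths = np.array(list(beta.values()))
    errs, covered = [], []
    for seed in range(200, 230):
        cfg = GeneratorConfig(n_sites=100, n_studies=15, seed=seed, beta=beta,
                              nonlinear_strength=0.0, noise_covariates=())
        frame, gt = covariate_level_frame(cfg)
        frame = frame.drop(columns=list(beta)).merge(
            gt.site_z.reset_index(), on="site_id")
        model = PoissonRegression(covariates=list(beta)).fit(
            frame, frame["patients_enrolled"])
        est = model.coef_[list(beta)].to_numpy()
        se = model.coef_se_[list(beta)].to_numpy()
        errs.append(est - truths)
        covered.append(np.abs(est - truths) <= 1.96 * se)
    errs = np.array(errs)
    assert np.abs(errs.mean(axis=0)).max() < 0.02
    coverage = np.array(covered).mean()
    assert 0.90 <= coverage <= 0.99
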