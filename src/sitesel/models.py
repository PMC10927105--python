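"""Baselines and Poisson-framed learners with a uniform fit/predict contract.

Enrollment counts are modeled as Poisson with the enrollment-months as the
exposure period.  All estimators are scikit-learn compatible (``fit`` /
``predict`` / ``get_params``) and take a feature DataFrame that carries the
site id and exposure in named columns next to the covariates:

* :class:`MedianBaseline` — the train-set median count for every row;
* :class:`SiteBaseline` — the site's historical median count, falling back
  to the median of per-site medians for unseen sites;
* :class:`PoissonRegression` — linear Poisson GLM with log-exposure offset;
* :class:`PoissonForest` — random forest on rates ``y/E`` with exposure
  sample weights (forests have no native offset);
* :class:`PoissonBoosting` — gradient boosting with the Poisson deviance
  objective and log-exposure as per-row base margin.

``exposure_mode`` controls how the exposure enters: ``"offset"`` (pure
rate model, prediction proportional to exposure), ``"feature"`` (months as
an ordinary covariate) or ``"both"``.

:func:`tune` runs a random hyperparameter search scored by out-of-fold
Spearman correlation on site-level cross-validation folds, mirroring the
practice of optimizing site-ranking ability rather than squared error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xgboost as xgb
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor

from .errors import ConfigError
from .recruitment_features import (
    EXPOSURE_COLUMN,
    FeatureTable,
    KEY_COLUMNS,
    TARGET_COLUMN,
)

__all__ = [
    "ModelSpec",
    "MedianBaseline",
    "SiteBaseline",
    "PoissonRegression",
    "PoissonForest",
    "PoissonBoosting",
    "ConvergenceError",
    "make_estimator",
    "fit_median_baseline",
    "fit_site_baseline",
    "fit_linear_poisson",
    "fit_tree_model",
    "tune",
    "Choice",
    "Uniform",
    "LogUniform",
    "IntRange",
    "DEFAULT_GRIDS",
]

RESERVED_COLUMNS = set(KEY_COLUMNS) | {TARGET_COLUMN, EXPOSURE_COLUMN}

FAMILIES = (
    "median_baseline",
    "site_baseline",
    "linear_poisson",
    "random_forest",
    "gradient_boosting",
)


class ConvergenceError(RuntimeError):
    """The iterative fit did not converge."""


@dataclass
class ModelSpec:
    """Declarative description of a model to fit."""

    family: str
    hyperparameters: dict[str, Any] = dc_field(default_factory=dict)
    exposure_mode: str = "offset"
    selected_covariates: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(
                f"unknown model family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.exposure_mode not in ("offset", "feature", "both"):
            raise ConfigError(f"unknown exposure_mode {self.exposure_mode!r}")


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, FeatureTable):
        return rows.frame
    return rows


def _covariate_columns(X: pd.DataFrame, covariates: Sequence[str] | None) -> list[str]:
    if covariates is not None:
        missing = [c for c in covariates if c not in X.columns]
        if missing:
            raise ConfigError(f"covariates absent from the table: {missing}")
        return [c for c in covariates if c != EXPOSURE_COLUMN]
    return [
        c
        for c in X.columns
        if c not in RESERVED_COLUMNS and pd.api.types.is_numeric_dtype(X[c])
    ]


# ---------------------------------------------------------------------------
# baselines


class MedianBaseline(BaseEstimator, RegressorMixin):
    """Predict the train-set median enrollment count for every row.

    With ``use_exposure=True`` the train median of rates ``y/E`` is scaled
    by each row's exposure instead (off by default; the plain-count form is
    the conventional comparator).
    """

    def __init__(self, use_exposure: bool = False,
                 exposure_col: str = EXPOSURE_COLUMN):
        self.use_exposure = use_exposure
        self.exposure_col = exposure_col

    def fit(self, X, y) -> "MedianBaseline":
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("cannot fit a baseline on an empty training set")
        if self.use_exposure:
            e = np.asarray(X[self.exposure_col], dtype=float)
            self.median_ = float(np.median(y / e))
        else:
            self.median_ = float(np.median(y))
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X)
        if self.use_exposure:
            return self.median_ * np.asarray(X[self.exposure_col], dtype=float)
        return np.full(len(X), self.median_)


class SiteBaseline(BaseEstimator, RegressorMixin):
    """Predict a site's historical median enrollment count.

    By default the per-site medians come from the training rows, and sites
    without training history get the median over the per-site medians of
    the training set.  When an enrollment ``history`` frame (columns
    ``study_id``, ``site_id``, ``patients_enrolled``) is supplied, a site
    absent from training is instead predicted from its own history with the
    current study left out — the industry practice of quoting a site's
    historical enrollment works for any site with past studies, not only
    those in the training partition.
    """

    def __init__(self, site_col: str = "site_id", use_exposure: bool = False,
                 exposure_col: str = EXPOSURE_COLUMN,
                 history: pd.DataFrame | None = None):
        self.site_col = site_col
        self.use_exposure = use_exposure
        self.exposure_col = exposure_col
        self.history = history

    def fit(self, X, y) -> "SiteBaseline":
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("cannot fit a baseline on an empty training set")
        target = y
        if self.use_exposure:
            target = y / np.asarray(X[self.exposure_col], dtype=float)
        per_site = (
            pd.Series(target, index=pd.Index(X[self.site_col], name="site"))
            .groupby(level=0)
            .median()
        )
        self.site_medians_ = per_site.to_dict()
        self.fallback_ = float(per_site.median())
        return self

    def _history_median(self, site_id: str, study_id) -> float | None:
        hist = self.history
        rows = hist[(hist[self.site_col] == site_id)
                    & (hist["study_id"] != study_id)]
        if rows.empty:
            return None
        return float(rows[TARGET_COLUMN].median())

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X)
        vals = X[self.site_col].map(self.site_medians_)
        if self.history is not None and vals.isna().any():
            fills = [
                self._history_median(site, study)
                for site, study in zip(
                    X.loc[vals.isna(), self.site_col],
                    X.loc[vals.isna(), "study_id"],
                )
            ]
            vals.loc[vals.isna()] = [
                self.fallback_ if f is None else f for f in fills
            ]
        vals = vals.fillna(self.fallback_).to_numpy()
        if self.use_exposure:
            vals = vals * np.asarray(X[self.exposure_col], dtype=float)
        return vals.astype(float)


# ---------------------------------------------------------------------------
# linear Poisson GLM


class PoissonRegression(BaseEstimator, RegressorMixin):
    """Poisson GLM of counts with mean ``E * exp(b0 + b.x)``.

    The log of the exposure enters as an offset (``exposure_mode="offset"``,
    the default), as an ordinary covariate (``"feature"``) or both.  On a
    rank-deficient design the fit falls back to a tiny ridge penalty
    (1e-6) with a warning; a non-converged IRLS raises
    :class:`ConvergenceError` with the iteration count.
    """

    def __init__(
        self,
        covariates: list[str] | None = None,
        exposure_mode: str = "offset",
        exposure_col: str = EXPOSURE_COLUMN,
        max_iter: int = 200,
        ridge_alpha: float = 1e-6,
    ):
        self.covariates = covariates
        self.exposure_mode = exposure_mode
        self.exposure_col = exposure_col
        self.max_iter = max_iter
        self.ridge_alpha = ridge_alpha

    def _design(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        cols = list(self.feature_names_)
        mat = X[cols].to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(X)), mat])
        exposure = np.asarray(X[self.exposure_col], dtype=float)
        return design, exposure

    def fit(self, X, y) -> "PoissonRegression":
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        cols = _covariate_columns(X, self.covariates)
        if self.exposure_mode in ("feature", "both"):
            cols = cols + [self.exposure_col]
        self.feature_names_ = list(cols)
        mat = X[cols].to_numpy(dtype=float)
        exposure = np.asarray(X[self.exposure_col], dtype=float)
        if np.any(exposure <= 0):
            raise ValueError("exposure must be strictly positive")
        offset = (
            np.log(exposure)
            if self.exposure_mode in ("offset", "both")
            else np.zeros(len(X))
        )

        # standardize internally for IRLS stability; coefficients are mapped
        # back to the original scale exactly, so this is a pure
        # reparametrization.  Zero-variance columns carry no information and
        # get coefficient 0.
        mean = mat.mean(axis=0)
        std = mat.std(axis=0, ddof=0)
        keep = std > 0
        z = (mat[:, keep] - mean[keep]) / std[keep]
        design = np.column_stack([np.ones(len(X)), z])

        model = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset)
        self.used_ridge_ = False
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn(
                "collinear covariates detected; falling back to a ridge "
                f"penalty of {self.ridge_alpha}",
                stacklevel=2,
            )
            res = model.fit_regularized(
                alpha=self.ridge_alpha, L1_wt=0.0, maxiter=self.max_iter
            )
            se_z = np.full(design.shape[1], np.nan)
            self.used_ridge_ = True
        else:
            res = model.fit(maxiter=self.max_iter)
            if not getattr(res, "converged", True):
                raise ConvergenceError(
                    f"Poisson IRLS did not converge in {self.max_iter} iterations"
                )
            se_z = np.asarray(res.bse, dtype=float)
        params = np.asarray(res.params, dtype=float)

        coef = np.zeros(len(cols))
        coef[keep] = params[1:] / std[keep]
        se = np.full(len(cols), np.nan)
        se[keep] = se_z[1:] / std[keep]
        self.intercept_ = float(
            params[0] - np.sum(params[1:] * mean[keep] / std[keep])
        )
        self.coef_ = pd.Series(coef, index=self.feature_names_)
        self.coef_se_ = pd.Series(se, index=self.feature_names_)
        self.result_ = res
        return self

    def _margin(self, X: pd.DataFrame) -> np.ndarray:
        design, _ = self._design(X)
        return design @ np.concatenate([[self.intercept_], self.coef_.to_numpy()])

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X)
        rate = np.exp(self._margin(X))
        if self.exposure_mode in ("offset", "both"):
            exposure = np.asarray(X[self.exposure_col], dtype=float)
            return exposure * rate
        return rate

    def attributions(self, X) -> tuple[pd.DataFrame, float]:
        """Additive per-row covariate attributions on the log-rate margin.

        For a linear model with independent features the exact additive
        attribution is ``b_j * (x_j - mean(x_j))`` over the given rows; the
        base value is the mean margin, so attributions plus base reproduce
        each row's margin exactly.
        """
        X = _as_frame(X)
        mat = X[self.feature_names_].to_numpy(dtype=float)
        mean = mat.mean(axis=0)
        contrib = (mat - mean) * self.coef_.to_numpy()
        base = float(self.intercept_ + mean @ self.coef_.to_numpy())
        return pd.DataFrame(contrib, index=X.index,
                            columns=self.feature_names_), base


# ---------------------------------------------------------------------------
# tree ensembles


class PoissonForest(BaseEstimator, RegressorMixin):
    """Random forest on enrollment rates with exposure sample weights.

    Forests have no native offset, so the Poisson mean structure is
    preserved approximately by regressing ``y/E`` with per-row weight ``E``
    (Poisson split criterion) and predicting ``rate * E``.  With
    ``exposure_mode="both"`` (default) the months also enter as a feature;
    with ``"feature"`` the forest fits raw counts with months as a feature.
    """

    def __init__(
        self,
        covariates: list[str] | None = None,
        exposure_mode: str = "both",
        exposure_col: str = EXPOSURE_COLUMN,
        n_estimators: int = 300,
        max_depth: int | None = None,
        min_samples_leaf: int = 5,
        max_features: float | str = 0.8,
        seed: int = 0,
    ):
        self.covariates = covariates
        self.exposure_mode = exposure_mode
        self.exposure_col = exposure_col
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.seed = seed

    def fit(self, X, y) -> "PoissonForest":
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        cols = _covariate_columns(X, self.covariates)
        if self.exposure_mode in ("feature", "both"):
            cols = cols + [self.exposure_col]
        self.feature_names_ = list(cols)
        exposure = np.asarray(X[self.exposure_col], dtype=float)
        self._forest = RandomForestRegressor(
            n_estimators=self.n_estimators,
            criterion="poisson",
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=1,
        )
        mat = X[cols].to_numpy(dtype=float)
        if self.exposure_mode == "feature":
            self._forest.fit(mat, y)
        else:
            self._forest.fit(mat, y / exposure, sample_weight=exposure)
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X)
        mat = X[self.feature_names_].to_numpy(dtype=float)
        pred = self._forest.predict(mat)
        if self.exposure_mode == "feature":
            return pred
        return pred * np.asarray(X[self.exposure_col], dtype=float)


class PoissonBoosting(BaseEstimator, RegressorMixin):
    """Gradient-boosted trees with the Poisson deviance objective.

    The log exposure enters as a per-row base margin during training, so
    the trees learn the log *rate*; prediction is ``E * exp(margin)``,
    making predictions exactly proportional to exposure under
    ``exposure_mode="offset"``.  Default hyperparameters are moderate
    (shallow trees, slow learning rate, child-weight regularization) as is
    standard for tabular count data of a few thousand rows.
    """

    def __init__(
        self,
        covariates: list[str] | None = None,
        exposure_mode: str = "both",
        exposure_col: str = EXPOSURE_COLUMN,
        n_estimators: int = 400,
        learning_rate: float = 0.05,
        max_depth: int = 3,
        min_child_weight: float = 10.0,
        subsample: float = 0.8,
        colsample_bytree: float = 0.8,
        reg_lambda: float = 1.0,
        seed: int = 0,
    ):
        self.covariates = covariates
        self.exposure_mode = exposure_mode
        self.exposure_col = exposure_col
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.min_child_weight = min_child_weight
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.reg_lambda = reg_lambda
        self.seed = seed

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.feature_names_].to_numpy(dtype=float)

    def fit(self, X, y) -> "PoissonBoosting":
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        cols = _covariate_columns(X, self.covariates)
        if self.exposure_mode in ("feature", "both"):
            cols = cols + [self.exposure_col]
        self.feature_names_ = list(cols)
        exposure = np.asarray(X[self.exposure_col], dtype=float)
        if np.any(exposure <= 0):
            raise ValueError("exposure must be strictly positive")
        self._xgb = xgb.XGBRegressor(
            objective="count:poisson",
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            min_child_weight=self.min_child_weight,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            reg_lambda=self.reg_lambda,
            random_state=self.seed,
            base_score=1.0,
            tree_method="hist",
            n_jobs=1,
            verbosity=0,
        )
        margin = (
            np.log(exposure)
            if self.exposure_mode in ("offset", "both")
            else np.zeros(len(X))
        )
        self._xgb.fit(self._matrix(X), y, base_margin=margin)
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X)
        raw = self._xgb.predict(self._matrix(X), output_margin=True)
        rate = np.exp(raw.astype(float))
        if self.exposure_mode in ("offset", "both"):
            return np.asarray(X[self.exposure_col], dtype=float) * rate
        return rate

    def attributions(self, X) -> tuple[pd.DataFrame, float]:
        """Exact per-row TreeSHAP attributions on the log-rate margin.

        Attributions plus the base value reconstruct the raw margin
        (excluding the exposure offset) for every row.
        """
        X = _as_frame(X)
        booster = self._xgb.get_booster()
        dmat = xgb.DMatrix(self._matrix(X), feature_names=self.feature_names_)
        contribs = booster.predict(dmat, pred_contribs=True)
        base = float(contribs[0, -1]) if len(contribs) else 0.0
        return (
            pd.DataFrame(contribs[:, :-1], index=X.index,
                         columns=self.feature_names_),
            base,
        )


# ---------------------------------------------------------------------------
# spec-driven construction and fit helpers


_FAMILY_CLASSES = {
    "median_baseline": MedianBaseline,
    "site_baseline": SiteBaseline,
    "linear_poisson": PoissonRegression,
    "random_forest": PoissonForest,
    "gradient_boosting": PoissonBoosting,
}

_DEFAULT_EXPOSURE_MODE = {
    "linear_poisson": "offset",
    "random_forest": "both",
    "gradient_boosting": "both",
}


def make_estimator(spec: ModelSpec) -> BaseEstimator:
    """Instantiate the estimator a :class:`ModelSpec` describes.

    Unknown hyperparameter names raise :class:`~sitesel.errors.ConfigError`.
    """
    cls = _FAMILY_CLASSES[spec.family]
    kwargs: dict[str, Any] = dict(spec.hyperparameters)
    valid = set(cls().get_params())
    unknown = [k for k in kwargs if k not in valid]
    if unknown:
        raise ConfigError(
            f"unknown hyperparameter(s) for {spec.family}: {unknown}"
        )
    if spec.family in _DEFAULT_EXPOSURE_MODE:
        kwargs.setdefault("exposure_mode", spec.exposure_mode)
        kwargs.setdefault("covariates", spec.selected_covariates)
    if "seed" in valid:
        kwargs.setdefault("seed", spec.seed)
    return cls(**kwargs)


def _xy(rows) -> tuple[pd.DataFrame, np.ndarray]:
    frame = _as_frame(rows)
    return frame, frame[TARGET_COLUMN].to_numpy(dtype=float)


def fit_median_baseline(rows) -> MedianBaseline:
    X, y = _xy(rows)
    return MedianBaseline().fit(X, y)


def fit_site_baseline(rows) -> SiteBaseline:
    X, y = _xy(rows)
    return SiteBaseline().fit(X, y)


def fit_linear_poisson(rows, spec: ModelSpec | None = None) -> PoissonRegression:
    spec = spec or ModelSpec(family="linear_poisson")
    X, y = _xy(rows)
    est = make_estimator(spec)
    return est.fit(X, y)


def fit_tree_model(rows, spec: ModelSpec) -> BaseEstimator:
    if spec.family not in ("random_forest", "gradient_boosting"):
        raise ConfigError(f"fit_tree_model expects a tree family, got {spec.family}")
    X, y = _xy(rows)
    est = make_estimator(spec)
    return est.fit(X, y)


# ---------------------------------------------------------------------------
# random hyperparameter search


@dataclass(frozen=True)
class Choice:
    options: tuple

    def sample(self, rng: np.random.Generator):
        return self.options[int(rng.integers(len(self.options)))]


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class LogUniform:
    low: float
    high: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))


@dataclass(frozen=True)
class IntRange:
    low: int
    high: int  # inclusive

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.low, self.high + 1))


DEFAULT_GRIDS: dict[str, dict[str, Any]] = {
    # stand-in search space documented in the methods note
    "gradient_boosting": {
        "max_depth": Choice(tuple(range(2, 9))),
        "learning_rate": LogUniform(0.01, 0.3),
        "n_estimators": IntRange(50, 500),
        "min_child_weight": IntRange(1, 10),
        "subsample": Uniform(0.5, 1.0),
    },
    "random_forest": {
        "n_estimators": IntRange(100, 500),
        "max_depth": Choice((None, 4, 6, 8, 12)),
        "min_samples_leaf": IntRange(1, 10),
        "max_features": Uniform(0.3, 1.0),
    },
    "linear_poisson": {},
}


def _sample_spec(
    family: str, grid: Mapping[str, Any], rng: np.random.Generator, seed: int
) -> ModelSpec:
    params = {}
    for name, space in grid.items():
        if isinstance(space, (list, tuple)):
            space = Choice(tuple(space))
        params[name] = space.sample(rng)
    return ModelSpec(
        family=family,
        hyperparameters=params,
        exposure_mode=_DEFAULT_EXPOSURE_MODE.get(family, "offset"),
        seed=seed,
    )


def tune(
    rows,
    family: str,
    grid: Mapping[str, Any] | None = None,
    n_trials: int = 128,
    cv_folds: int = 5,
    seed: int = 0,
    covariates: list[str] | None = None,
) -> ModelSpec:
    """Random hyperparameter search scored by out-of-fold Spearman.

    Samples ``n_trials`` hyperparameter sets uniformly at random from the
    grid, scores each by the mean Spearman correlation of out-of-fold
    predictions against the observed counts over site-level CV folds, and
    returns the best spec (ties go to the first encountered).  Candidates
    that fail to fit or produce constant predictions score worst.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    if grid is None:
        grid = DEFAULT_GRIDS.get(family, {})
    frame, y = _xy(rows)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))

    # site-level folds: every row of a site shares its fold
    sites = np.asarray(sorted(set(frame["site_id"])))
    perm = rng.permutation(len(sites))
    fold_of_site = {sites[p]: i % cv_folds for i, p in enumerate(perm)}
    folds = frame["site_id"].map(fold_of_site).to_numpy()

    best_spec: ModelSpec | None = None
    best_score = -np.inf
    for _ in range(n_trials):
        spec = _sample_spec(family, grid, rng, seed)
        if covariates is not None:
            spec.selected_covariates = list(covariates)
        fold_scores = []
        try:
            for k in range(cv_folds):
                train_mask = folds != k
                test_mask = ~train_mask
                if test_mask.sum() < 2 or train_mask.sum() < 2:
                    continue
                est = make_estimator(spec)
                est.fit(frame[train_mask], y[train_mask])
                pred = est.predict(frame[test_mask])
                rho = stats.spearmanr(pred, y[test_mask]).statistic
                fold_scores.append(0.0 if np.isnan(rho) else float(rho))
        except Exception:
            fold_scores = []
        score = float(np.mean(fold_scores)) if fold_scores else -np.inf
        if score > best_score:
            best_score = score
            best_spec = spec
    assert best_spec is not None
    best_spec.selected_covariates = list(covariates) if covariates else None
    return best_spec
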