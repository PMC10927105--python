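"""Enrollment-history covariates and the model-ready feature table.

For every (study, site) row the covariates summarize the site's past
enrollment over a five-year window indexed on the site open date
(half-open: past open dates in ``[open - 5y, open)``):

* median / EWMA of patients per month (pppm),
* median / EWMA of the site's within-study percentile rank in enrolled
  patients,
* median / EWMA / sum of enrolled patients,

plus the site open year, joined with the HCO-level real-world-data
aggregates.  EWMA weights decay with the age of the past study,
``w = 0.5 ** (age_years / half_life)`` with a two-year default half life.

Clipping and imputation follow the claims-covariate conventions: per
covariate the 97.5th percentile of the *training* rows is the upper bound
applied to all rows (right-side clipping, as the covariates are
gamma-distributed and right-skewed), then missing values are imputed by 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort_rwd import HCO_AGGREGATE_COLUMNS
from .data_model import StudySiteEnrollment, to_frame
from .errors import ConfigError, DataError

__all__ = [
    "FeatureTable",
    "HISTORY_COLUMNS",
    "COVARIATE_COLUMNS",
    "history_window",
    "pppm",
    "study_rank",
    "ewma",
    "history_features",
    "assemble",
    "ClipImputer",
    "clip_and_impute",
]

HISTORY_COLUMNS = [
    "median_pppm_5y",
    "ewma_pppm_5y",
    "median_rank_5y",
    "ewma_rank_5y",
    "median_enrolled_5y",
    "ewma_enrolled_5y",
    "sum_enrolled_5y",
]

COVARIATE_COLUMNS = ["site_open_year"] + HISTORY_COLUMNS + HCO_AGGREGATE_COLUMNS

KEY_COLUMNS = ["study_id", "site_id"]
TARGET_COLUMN = "patients_enrolled"
EXPOSURE_COLUMN = "enrollment_months"

WINDOW_YEARS = 5
DAYS_PER_YEAR = 365.25


@dataclass
class FeatureTable:
    """(study, site)-keyed covariate matrix with target and exposure.

    ``frame`` holds keys, target, exposure and covariates; missing
    covariate values are NaN until :func:`clip_and_impute`, after which
    ``clip_bounds`` stores the per-covariate upper bound used and
    ``imputed`` flags the cells that were filled with 0.
    """

    frame: pd.DataFrame
    covariates: list[str] = field(default_factory=lambda: list(COVARIATE_COLUMNS))
    clip_bounds: dict[str, float] | None = None
    imputed: pd.DataFrame | None = None

    @property
    def y(self) -> pd.Series:
        return self.frame[TARGET_COLUMN]

    @property
    def exposure(self) -> pd.Series:
        return self.frame[EXPOSURE_COLUMN]

    def rows_for_sites(self, site_ids: Iterable[str]) -> pd.DataFrame:
        wanted = set(site_ids)
        return self.frame[self.frame["site_id"].isin(wanted)]


def _enrollment_frame(enrollment) -> pd.DataFrame:
    if isinstance(enrollment, pd.DataFrame):
        frame = enrollment.copy()
    else:
        frame = to_frame(list(enrollment), StudySiteEnrollment)
    frame["site_open_date"] = pd.to_datetime(frame["site_open_date"])
    return frame


def history_window(
    enrollment, site_id: str, open_date
) -> pd.DataFrame:
    """The site's past enrollment rows with open date in ``[open - 5y, open)``.

    Rows lacking a site open date are excluded; a past study opening on the
    current open date is excluded (right-open), one exactly five years
    earlier is included (left-closed).
    """
    frame = _enrollment_frame(enrollment)
    open_ts = pd.Timestamp(open_date)
    lo = open_ts - pd.DateOffset(years=WINDOW_YEARS)
    mask = (
        (frame["site_id"] == site_id)
        & frame["site_open_date"].notna()
        & (frame["site_open_date"] >= lo)
        & (frame["site_open_date"] < open_ts)
    )
    return frame.loc[mask]


def pppm(row) -> float:
    """Patients per month: enrolled count over enrollment-months exposure."""
    months = row["enrollment_months"] if not isinstance(row, StudySiteEnrollment) \
        else row.enrollment_months
    count = row["patients_enrolled"] if not isinstance(row, StudySiteEnrollment) \
        else row.patients_enrolled
    if months <= 0:
        raise ValueError("enrollment_months must be positive")
    return float(count) / float(months)


def study_rank(enrollment, study_id: str, site_id: str) -> float:
    """Percentile rank of the site among the study's sites by enrolled count.

    Average ranks for ties, normalized by the number of sites in the study;
    1.0 is the top enroller.  A single-site study gives rank 1.0.
    """
    frame = _enrollment_frame(enrollment)
    study = frame[frame["study_id"] == study_id]
    if study.empty or site_id not in set(study["site_id"]):
        raise DataError(f"({study_id}, {site_id}) not present in enrollment")
    ranks = study["patients_enrolled"].rank(method="average")
    normalized = ranks / len(study)
    return float(normalized[study["site_id"] == site_id].iloc[0])


def _study_ranks(frame: pd.DataFrame) -> pd.Series:
    grouped = frame.groupby("study_id")["patients_enrolled"]
    return grouped.rank(method="average") / grouped.transform("size")


def ewma(
    values: Sequence[float], ages_years: Sequence[float], half_life_years: float = 2.0
) -> float:
    """Time-aware exponentially weighted average with the given half life.

    ``sum(w_i v_i) / sum(w_i)`` with ``w_i = 0.5 ** (age_i / half_life)``;
    NaN on empty input (the missing marker).
    """
    if half_life_years <= 0:
        raise ConfigError("half_life_years must be positive")
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages_years, dtype=float)
    if values.shape != ages.shape:
        raise ValueError("values and ages must have equal length")
    if values.size == 0:
        return float("nan")
    if np.any(ages < 0):
        raise ValueError("ages must be >= 0")
    w = 0.5 ** (ages / half_life_years)
    return float(np.sum(w * values) / np.sum(w))


def history_features(
    window: pd.DataFrame,
    current_open_date,
    ranks: pd.Series | None = None,
    half_life_years: float = 2.0,
) -> dict[str, float]:
    """The seven five-year history covariates for one (study, site) row.

    ``ranks`` maps the window rows (by index) to their within-study
    percentile ranks; EWMA ages are the year gaps between past and current
    open dates.  An empty window yields NaN for all seven (missing; imputed
    to 0 downstream).
    """
    if window.empty:
        return {name: float("nan") for name in HISTORY_COLUMNS}
    open_ts = pd.Timestamp(current_open_date)
    ages = (
        (open_ts - pd.to_datetime(window["site_open_date"]))
        .dt.days.to_numpy() / DAYS_PER_YEAR
    )
    counts = window["patients_enrolled"].to_numpy(dtype=float)
    months = window["enrollment_months"].to_numpy(dtype=float)
    pppm_vals = counts / months
    if ranks is None:
        rank_vals = np.full(len(window), np.nan)
    else:
        rank_vals = ranks.loc[window.index].to_numpy(dtype=float)
    return {
        "median_pppm_5y": float(np.median(pppm_vals)),
        "ewma_pppm_5y": ewma(pppm_vals, ages, half_life_years),
        "median_rank_5y": float(np.median(rank_vals)),
        "ewma_rank_5y": ewma(rank_vals, ages, half_life_years),
        "median_enrolled_5y": float(np.median(counts)),
        "ewma_enrolled_5y": ewma(counts, ages, half_life_years),
        "sum_enrolled_5y": float(np.sum(counts)),
    }


def assemble(
    enrollment,
    hco_aggregates: pd.DataFrame | None = None,
    half_life_years: float = 2.0,
) -> FeatureTable:
    """Join history covariates and HCO aggregates into the feature table.

    One row per enrollment row; sites absent from the aggregates get
    missing (NaN) real-world-data covariates.  Duplicate (study, site)
    rows are a data error.
    """
    frame = _enrollment_frame(enrollment)
    if frame.duplicated(subset=KEY_COLUMNS).any():
        dupes = frame.loc[frame.duplicated(subset=KEY_COLUMNS), KEY_COLUMNS]
        raise DataError(f"duplicate (study, site) rows: {dupes.values.tolist()[:5]}")
    ranks = _study_ranks(frame)

    out = frame[KEY_COLUMNS + ["site_open_date", TARGET_COLUMN,
                               EXPOSURE_COLUMN]].copy()
    out["site_open_year"] = frame["site_open_date"].dt.year.astype(float)

    hist_rows = []
    # per-site windows over the site's own history
    open_dates = frame["site_open_date"]
    for idx in frame.index:
        site_id = frame.at[idx, "site_id"]
        open_ts = open_dates[idx]
        lo = open_ts - pd.DateOffset(years=WINDOW_YEARS)
        mask = (
            (frame["site_id"] == site_id)
            & open_dates.notna()
            & (open_dates >= lo)
            & (open_dates < open_ts)
        )
        window = frame.loc[mask]
        hist_rows.append(history_features(window, open_ts, ranks, half_life_years))
    hist = pd.DataFrame(hist_rows, index=frame.index)
    out = pd.concat([out, hist], axis=1)

    if hco_aggregates is None:
        for col in HCO_AGGREGATE_COLUMNS:
            out[col] = np.nan
    else:
        agg = hco_aggregates.reindex(columns=HCO_AGGREGATE_COLUMNS)
        out = out.merge(
            agg, how="left", left_on="site_id", right_index=True
        )
    out = out.drop(columns=["site_open_date"])
    return FeatureTable(frame=out)


class ClipImputer(BaseEstimator, TransformerMixin):
    """Right-side outlier clipping plus impute-missing-with-zero.

    ``fit`` stores, per column, the ``percentile``-th percentile (linear
    interpolation between order statistics) of the non-missing training
    values; ``transform`` caps values above the bound and fills NaN with 0.
    Columns that are entirely missing on the training rows get bound 0 with
    a warning.  Idempotent: transforming already-transformed data is a no-op.
    """

    def __init__(self, percentile: float = 97.5, columns: list[str] | None = None):
        self.percentile = percentile
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None) -> "ClipImputer":
        cols = self.columns if self.columns is not None else list(X.columns)
        bounds: dict[str, float] = {}
        for col in cols:
            vals = pd.to_numeric(X[col], errors="coerce").dropna().to_numpy()
            if vals.size == 0:
                warnings.warn(
                    f"covariate {col!r} entirely missing on training rows; "
                    "clip bound set to 0",
                    stacklevel=2,
                )
                bounds[col] = 0.0
            else:
                bounds[col] = float(
                    np.percentile(vals, self.percentile, method="linear")
                )
        self.bounds_ = bounds
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col, bound in self.bounds_.items():
            vals = pd.to_numeric(out[col], errors="coerce")
            out[col] = vals.clip(upper=bound).fillna(0.0)
        return out


def clip_and_impute(
    table: FeatureTable,
    train_keys: Iterable[tuple[str, str]] | pd.Series | np.ndarray,
    percentile: float = 97.5,
) -> FeatureTable:
    """Clip covariates with bounds from the training rows, impute missing
    with 0, and record bounds plus imputation flags.

    ``train_keys`` is either a boolean row mask or an iterable of
    (study_id, site_id) pairs; bounds are estimated on those rows only and
    applied to the whole table (no test-set leakage into the bounds).
    """
    frame = table.frame
    if isinstance(train_keys, (pd.Series, np.ndarray)) and \
            getattr(train_keys, "dtype", None) == bool:
        mask = pd.Series(np.asarray(train_keys), index=frame.index)
    else:
        wanted = set(map(tuple, train_keys))
        mask = frame.apply(
            lambda row: (row["study_id"], row["site_id"]) in wanted, axis=1
        )
        if not mask.any():
            raise ConfigError("train_keys select no rows of the table")
    clipper = ClipImputer(percentile=percentile, columns=table.covariates)
    clipper.fit(frame.loc[mask])
    imputed = frame[table.covariates].isna()
    new_frame = frame.copy()
    new_frame[table.covariates] = clipper.transform(frame[table.covariates])
    return replace(
        table,
        frame=new_frame,
        clip_bounds=dict(clipper.bounds_),
        imputed=imputed,
    )
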