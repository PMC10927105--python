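"""History-window covariates, EWMA, ranks and clipping, against closed
forms and hand arithmetic."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sitesel.data_model import StudySiteEnrollment
from sitesel.errors import DataError
from sitesel.recruitment_features import (
    HISTORY_COLUMNS,
    ClipImputer,
    assemble,
    clip_and_impute,
    ewma,
    history_features,
    history_window,
    pppm,
    study_rank,
)


def row(study="S1", site="H1", open_date="2020-01-01", months=10.0, enrolled=5):
    open_d = dt.date.fromisoformat(open_date)
    return StudySiteEnrollment(
        study_id=study,
        site_id=site,
        site_open_date=open_d,
        first_subject_date=None,
        last_subject_date=None,
        enrollment_months=months,
        patients_enrolled=enrolled,
    )


class TestHistoryWindow:
    def test_no_prior_studies_empty(self):
        rows = [row("S1", open_date="2020-01-01")]
        assert history_window(rows, "H1", dt.date(2020, 1, 1)).empty

    def test_five_year_half_open_window(self):
        rows = [
            row("A", open_date="2019-01-01"),  # 1y before: in
            row("B", open_date="2016-01-01"),  # 4y before: in
            row("C", open_date="2014-01-01"),  # 6y before: out
            row("D", open_date="2015-01-01"),  # exactly 5y: in (left-closed)
            row("E", open_date="2020-01-01"),  # same day: out (right-open)
        ]
        window = history_window(rows, "H1", dt.date(2020, 1, 1))
        assert sorted(window["study_id"]) == ["A", "B", "D"]

    def test_other_sites_excluded(self):
        rows = [row("A", site="H2", open_date="2019-01-01")]
        assert history_window(rows, "H1", dt.date(2020, 1, 1)).empty


class TestPppm:
    @pytest.mark.parametrize(
        "enrolled,months,expected", [(12, 6.0, 2.0), (0, 3.0, 0.0), (9, 4.5, 2.0)]
    )
    def test_values(self, enrolled, months, expected):
        assert pppm({"patients_enrolled": enrolled,
                     "enrollment_months": months}) == expected


class TestStudyRank:
    def test_top_enroller_is_one(self):
        rows = [row("S", "H1", enrolled=10), row("S", "H2", enrolled=5),
                row("S", "H3", enrolled=1)]
        assert study_rank(rows, "S", "H1") == 1.0

    def test_middle_of_three(self):
        rows = [row("S", "H1", enrolled=10), row("S", "H2", enrolled=5),
                row("S", "H3", enrolled=1)]
        assert study_rank(rows, "S", "H2") == pytest.approx(2 / 3)

    def test_tied_pair_average_rank(self):
        rows = [row("S", "H1", enrolled=4), row("S", "H2", enrolled=4)]
        assert study_rank(rows, "S", "H1") == 0.75
        assert study_rank(rows, "S", "H2") == 0.75

    def test_single_site_study(self):
        assert study_rank([row("S", "H1")], "S", "H1") == 1.0


class TestEwma:
    def test_single_value_returned_as_is(self):
        assert ewma([3.5], [4.0], half_life_years=2.0) == 3.5

    def test_closed_form_half_life(self):
        assert ewma([2, 4], [0.0, 2.0], half_life_years=2.0) == \
            pytest.approx(8 / 3)

    def test_equal_ages_is_arithmetic_mean(self):
        assert ewma([1, 2, 6], [3, 3, 3], half_life_years=2.0) == 3.0

    def test_empty_is_missing(self):
        assert np.isnan(ewma([], [], 2.0))

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            ewma([1.0], [-0.5], 2.0)


class TestHistoryFeatures:
    def test_empty_window_all_missing(self):
        window = pd.DataFrame(
            columns=["site_open_date", "patients_enrolled", "enrollment_months"]
        )
        feats = history_features(window, dt.date(2020, 1, 1))
        assert set(feats) == set(HISTORY_COLUMNS)
        assert all(np.isnan(v) for v in feats.values())

    def test_two_rows_sum_and_median(self):
        rows = [row("A", open_date="2018-01-01", enrolled=3, months=3.0),
                row("B", open_date="2019-01-01", enrolled=5, months=5.0)]
        window = history_window(rows, "H1", dt.date(2020, 1, 1))
        feats = history_features(window, dt.date(2020, 1, 1))
        assert feats["sum_enrolled_5y"] == 8
        assert feats["median_enrolled_5y"] == 4
        assert feats["median_pppm_5y"] == 1.0

    def test_single_row_median_equals_ewma(self):
        rows = [row("A", open_date="2018-01-01", enrolled=7, months=2.0)]
        window = history_window(rows, "H1", dt.date(2020, 1, 1))
        ranks = pd.Series(1.0, index=window.index)
        feats = history_features(window, dt.date(2020, 1, 1), ranks)
        assert feats["median_pppm_5y"] == feats["ewma_pppm_5y"] == 3.5
        assert feats["median_enrolled_5y"] == feats["ewma_enrolled_5y"] == 7
        assert feats["median_rank_5y"] == feats["ewma_rank_5y"] == 1.0


class TestAssemble:
    def test_fully_crossed_rows(self):
        rows = [row(s, h) for s in ("S1", "S2") for h in ("H1", "H2")]
        table = assemble(rows)
        assert len(table.frame) == 4
        assert table.frame["site_open_year"].eq(2020).all()

    def test_duplicate_keys_rejected(self):
        with pytest.raises(DataError):
            assemble([row(), row()])

    def test_site_without_history_or_aggregates_flagged_missing(self):
        agg = pd.DataFrame({"n_patients": [50.0]},
                           index=pd.Index(["H1"], name="hco_id"))
        rows = [row("S1", "H1"), row("S1", "H2")]
        table = assemble(rows, agg)
        h1 = table.frame[table.frame["site_id"] == "H1"].iloc[0]
        h2 = table.frame[table.frame["site_id"] == "H2"].iloc[0]
        assert h1["n_patients"] == 50.0
        assert np.isnan(h2["n_patients"])
        assert np.isnan(h1["median_pppm_5y"])  # no history either

    def test_oracle_join_on_hand_fixture(self):
        """Assembled history features equal a brute-force recomputation."""
        rows = [
            row("S1", "H1", "2016-06-01", months=4.0, enrolled=2),
            row("S2", "H1", "2018-01-01", months=5.0, enrolled=10),
            row("S2", "H2", "2018-01-01", months=5.0, enrolled=4),
            row("S3", "H1", "2021-01-01", months=8.0, enrolled=6),
        ]
        table = assemble(rows)
        s3 = table.frame.set_index("study_id").loc["S3"]
        # window for (S3, H1): S1 opened 4.6y before, S2 3y before
        pppms = [2 / 4.0, 10 / 5.0]
        assert s3["median_pppm_5y"] == pytest.approx(np.median(pppms))
        assert s3["sum_enrolled_5y"] == 12
        # S1 is single-site (rank 1.0); S2 ranks: H1 top of 2 -> 1.0
        assert s3["median_rank_5y"] == 1.0
        ages = [(dt.date(2021, 1, 1) - dt.date(2016, 6, 1)).days / 365.25,
                (dt.date(2021, 1, 1) - dt.date(2018, 1, 1)).days / 365.25]
        w = [0.5 ** (a / 2.0) for a in ages]
        expected_ewma = (w[0] * 2 + w[1] * 10) / sum(w)
        assert s3["ewma_enrolled_5y"] == pytest.approx(expected_ewma)


class TestClipImpute:
    def test_percentile_bound_linear_interpolation(self):
        """40 train values 1..40: the 97.5th percentile is 39.025."""
        frame = pd.DataFrame({"x": np.arange(1.0, 41.0)})
        clipper = ClipImputer(columns=["x"]).fit(frame)
        assert clipper.bounds_["x"] == pytest.approx(39.025)
        out = clipper.transform(pd.DataFrame({"x": [40.0, 5.0]}))
        assert out["x"].tolist() == pytest.approx([39.025, 5.0])

    def test_values_below_bound_unchanged_and_idempotent(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, np.nan, 50.0]})
        clipper = ClipImputer(columns=["x"]).fit(frame.iloc[:2])
        once = clipper.transform(frame)
        twice = clipper.transform(once)
        pd.testing.assert_frame_equal(once, twice)
        assert once["x"].max() <= clipper.bounds_["x"]

    def test_missing_imputed_to_zero_and_flagged(self):
        rows = [row("S1", "H1"), row("S1", "H2"), row("S2", "H1")]
        table = assemble(rows)
        clipped = clip_and_impute(table, [("S1", "H1"), ("S1", "H2")])
        assert clipped.frame[clipped.covariates].notna().all().all()
        # S1 rows have no history: flagged imputed, value 0 after fill
        assert clipped.imputed.loc[0, "median_pppm_5y"]
        assert clipped.frame.loc[0, "median_pppm_5y"] == 0.0

    def test_entirely_missing_covariate_warns_bound_zero(self):
        frame = pd.DataFrame({"x": [np.nan, np.nan]})
        with pytest.warns(UserWarning, match="entirely missing"):
            clipper = ClipImputer(columns=["x"]).fit(frame)
        assert clipper.bounds_["x"] == 0.0


def test_no_future_leakage_from_later_studies():
    """Adding enrollment rows for studies opening at or after a row's open
    date leaves that row's features unchanged."""
    base = [
        row("S1", "H1", "2016-06-01", enrolled=2),
        row("S2", "H1", "2018-01-01", enrolled=10),
        row("S3", "H1", "2021-01-01", enrolled=6),
    ]
    future = [
        row("F1", "H1", "2021-01-01", enrolled=99),
        row("F2", "H1", "2023-05-01", enrolled=50),
    ]
    before = assemble(base).frame.set_index("study_id")
    after = assemble(base + future).frame.set_index("study_id")
    pd.testing.assert_frame_equal(before, after.loc[before.index])
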