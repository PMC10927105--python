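"""Site-level splitting, regression metrics, top/bottom-30% AUC and paired
significance testing.

Rows are split at *site* level — every (study, site) row of a site lands in
the same partition — so test performance measures generalization to unseen
sites.  Regression quality is reported as MAE, RMSE, Spearman rank
correlation and R² (reference only; models are optimized for ranking).
Ranking quality is additionally converted to a classification AUC: sites
are labeled by whether their actual enrollment is in the top (or bottom)
30%, and the continuous predicted enrollment is used as the score, with the
Mann–Whitney half-credit rule for tied score pairs.  A constant predictor
therefore scores exactly 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import ConfigError, DataError
from .recruitment_features import FeatureTable, TARGET_COLUMN

__all__ = [
    "SplitAssignment",
    "split_sites",
    "regression_metrics",
    "topk_labels",
    "auc",
    "paired_abs_error_test",
    "EvaluationReport",
    "evaluate_all",
    "TEST_METRIC_NAMES",
]

TEST_METRIC_NAMES = [
    "Test R2",
    "Test Spearman correlation coefficient",
    "Test RMSE",
    "Test MAE",
    "Test Top 30% AUC",
    "Test Bottom 30% AUC",
]


@dataclass(frozen=True)
class SplitAssignment:
    """Site-level train/test partition plus cross-validation folds."""

    partition: Mapping[str, str]  # site_id -> "train" | "test"
    folds: Mapping[str, int]  # train site_id -> fold 1..n_folds
    seed: int

    @property
    def train_sites(self) -> list[str]:
        return sorted(s for s, p in self.partition.items() if p == "train")

    @property
    def test_sites(self) -> list[str]:
        return sorted(s for s, p in self.partition.items() if p == "test")

    def mask(self, frame: pd.DataFrame, partition: str) -> pd.Series:
        return frame["site_id"].map(self.partition) == partition


def split_sites(
    site_ids: Sequence[str],
    train_frac: float = 0.8,
    seed: int = 0,
    n_folds: int = 5,
) -> SplitAssignment:
    """Random site-level split: first ``ceil(train_frac * n)`` shuffled sites
    train, the rest test; train sites get folds 1..n_folds round-robin."""
    if not 0.0 < train_frac < 1.0:
        raise ConfigError(f"train_frac must be in (0, 1), got {train_frac}")
    sites = sorted(set(site_ids))
    if len(sites) < 5:
        raise ConfigError("need at least 5 sites to split")
    rng = np.random.default_rng(seed)
    order = [sites[i] for i in rng.permutation(len(sites))]
    n_train = math.ceil(train_frac * len(order))
    partition = {s: ("train" if i < n_train else "test") for i, s in enumerate(order)}
    folds = {s: (i % n_folds) + 1 for i, s in enumerate(order[:n_train])}
    return SplitAssignment(partition=partition, folds=folds, seed=seed)


def regression_metrics(y, y_pred) -> dict[str, float | None]:
    """MAE, RMSE, Spearman and R².

    Spearman is reported as None when the predictions are constant (rank
    correlation undefined) — the baselines' "-" cells.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.size < 2:
        raise ValueError("y and y_pred must share a length of at least 2")
    err = y - y_pred
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else None
    if np.all(y_pred == y_pred[0]):
        rho = None
    else:
        rho = float(stats.spearmanr(y, y_pred).statistic)
        if np.isnan(rho):
            rho = None
    return {"MAE": mae, "RMSE": rmse, "Spearman": rho, "R2": r2}


def topk_labels(
    y,
    fraction: float = 0.3,
    direction: str = "top",
    ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Binary labels marking the ``ceil(fraction * n)`` largest (``top``) or
    smallest (``bottom``) values; boundary ties break by ascending id."""
    if not 0.0 < fraction <= 0.5:
        raise ConfigError(f"fraction must be in (0, 0.5], got {fraction}")
    if direction not in ("top", "bottom"):
        raise ConfigError(f"direction must be 'top' or 'bottom', got {direction!r}")
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 values to form top/bottom groups")
    ids = np.asarray(ids if ids is not None else [str(i) for i in range(n)])
    k = math.ceil(fraction * n)
    key = -y if direction == "top" else y
    order = np.lexsort((ids, key))
    labels = np.zeros(n, dtype=int)
    labels[order[:k]] = 1
    return labels


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: fraction of (positive, negative) pairs where the
    positive scores higher, with half credit for ties."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, scores))


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float | None
    n: int


def paired_abs_error_test(errors_a, errors_b) -> TTestResult:
    """Dependent t-test for paired samples on absolute errors.

    ``t = mean(d) / (sd(d) / sqrt(n))`` for differences ``d`` on identical
    rows, two-sided p from the t distribution with n-1 df; zero-variance
    differences give an undefined (None) p.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("paired errors must share a length of at least 3")
    d = a - b
    sd = float(np.std(d, ddof=1))
    n = int(d.size)
    if sd == 0.0:
        return TTestResult(t=0.0 if d.mean() == 0 else math.inf, p=None, n=n)
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return TTestResult(t=t, p=p, n=n)


@dataclass
class EvaluationReport:
    """Per-model train/test metrics plus pairwise significance tests."""

    metrics: dict[str, dict[str, dict[str, float | None]]]  # model -> split -> metric
    ttests: list[dict] = field(default_factory=list)
    fraction: float = 0.3

    def test_frame(self) -> pd.DataFrame:
        rows = {}
        for model, splits in self.metrics.items():
            m = splits["test"]
            rows[model] = {
                "Test R2": m["R2"],
                "Test Spearman correlation coefficient": m["Spearman"],
                "Test RMSE": m["RMSE"],
                "Test MAE": m["MAE"],
                "Test Top 30% AUC": m["AUC_top30"],
                "Test Bottom 30% AUC": m["AUC_bottom30"],
            }
        return pd.DataFrame.from_dict(rows, orient="index")[TEST_METRIC_NAMES]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"metrics": self.metrics, "ttests": self.ttests,
             "fraction": self.fraction},
            sort_keys=True,
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def _split_metrics(y, pred, ids, fraction) -> dict[str, float | None]:
    out = regression_metrics(y, pred)
    # identifying the bottom group means ranking by *low* predicted
    # enrollment, so the score sign flips with the direction
    for direction, sign, name in (
        ("top", 1.0, "AUC_top30"),
        ("bottom", -1.0, "AUC_bottom30"),
    ):
        try:
            labels = topk_labels(y, fraction, direction, ids=ids)
            out[name] = auc(sign * pred, labels)
        except ValueError:
            out[name] = None
    return out


def evaluate_all(
    fitted_models: Mapping[str, object],
    table: FeatureTable,
    split: SplitAssignment,
    fraction: float = 0.3,
) -> EvaluationReport:
    """Fill the per-model report for train and test rows.

    AUCs use the continuous predicted enrollment as score against actual
    top/bottom labels.  Pairwise dependent t-tests compare the models'
    absolute errors on the test rows.
    """
    frame = table.frame
    masks = {p: split.mask(frame, p) for p in ("train", "test")}
    for p, mask in masks.items():
        if mask.sum() < 2:
            raise DataError(f"{p} partition has fewer than 2 rows")
    metrics: dict[str, dict[str, dict[str, float | None]]] = {}
    test_abs_errors: dict[str, np.ndarray] = {}
    for name, model in fitted_models.items():
        metrics[name] = {}
        for part, mask in masks.items():
            rows = frame[mask]
            y = rows[TARGET_COLUMN].to_numpy(dtype=float)
            pred = np.asarray(model.predict(rows), dtype=float)
            metrics[name][part] = _split_metrics(
                y, pred, rows["site_id"].to_numpy(), fraction
            )
            if part == "test":
                test_abs_errors[name] = np.abs(y - pred)
    ttests = []
    names = list(fitted_models)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = paired_abs_error_test(test_abs_errors[a], test_abs_errors[b])
            ttests.append(
                {"model_a": a, "model_b": b, "t": res.t, "p": res.p, "n": res.n}
            )
    return EvaluationReport(metrics=metrics, ttests=ttests, fraction=fraction)
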