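"""Covariate importance, threshold selection and dependence curves.

Importance is the mean absolute additive attribution (Shapley value) of a
covariate over rows, computed on the model-margin (log-rate) scale —
exact TreeSHAP for the gradient-boosted model, the closed-form linear
attribution for the Poisson GLM.  Covariates whose importance falls below
a fixed threshold (0.005 by default) are removed from the covariate set;
importance is computed on training rows with the model fitted on all
covariates.  Dependence curves pair each row's covariate value with its
per-row attribution, the tabular form of a SHAP dependence plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from .errors import ConfigError

__all__ = [
    "AttributionError",
    "ImportanceReport",
    "importance",
    "select_covariates",
    "dependence",
    "DEFAULT_SHAP_THRESHOLD",
]

DEFAULT_SHAP_THRESHOLD = 0.005


class AttributionError(TypeError):
    """The model family does not support additive attributions."""


@dataclass
class ImportanceReport:
    """Mean |attribution| per covariate (margin units) and the selection
    they imply at the stored threshold."""

    importances: dict[str, float]  # ordered as the model's covariates
    threshold: float = DEFAULT_SHAP_THRESHOLD

    @property
    def selected(self) -> dict[str, bool]:
        return {c: v >= self.threshold for c, v in self.importances.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "importance": pd.Series(self.importances),
                "selected": pd.Series(self.selected),
            }
        ).rename_axis("covariate")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path)
        return path


def _attributions(model, rows) -> tuple[pd.DataFrame, float]:
    fn = getattr(model, "attributions", None)
    if fn is None:
        raise AttributionError(
            f"{type(model).__name__} does not support additive attributions "
            "(baselines and the random forest have none; use the linear or "
            "gradient-boosting model)"
        )
    return fn(rows)


def importance(
    model, rows, threshold: float = DEFAULT_SHAP_THRESHOLD
) -> ImportanceReport:
    """Mean absolute per-row attribution of each covariate on the log-rate
    margin over the given (training) rows."""
    contrib, _ = _attributions(model, rows)
    means = contrib.abs().mean(axis=0)
    return ImportanceReport(
        importances={c: float(means[c]) for c in contrib.columns},
        threshold=threshold,
    )


def select_covariates(report: ImportanceReport,
                      threshold: float | None = None) -> list[str]:
    """Covariates meeting the importance threshold, original order kept.

    Raises when nothing survives (the threshold is too high for the model's
    attribution scale).
    """
    thr = report.threshold if threshold is None else threshold
    kept = [c for c, v in report.importances.items() if v >= thr]
    if not kept:
        raise ConfigError(
            f"no covariate reaches importance {thr}; lower the threshold"
        )
    return kept


def dependence(model, rows, covariate: str) -> pd.DataFrame:
    """Per-row (covariate value, attribution) pairs for one covariate."""
    contrib, _ = _attributions(model, rows)
    if covariate not in contrib.columns:
        raise ConfigError(f"covariate {covariate!r} is not in the model")
    frame = rows.frame if hasattr(rows, "frame") else rows
    return pd.DataFrame(
        {"value": frame[covariate].to_numpy(dtype=float),
         "shap": contrib[covariate].to_numpy(dtype=float)}
    )
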