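"""Predictor preparation and variable selection.

Predictors extracted at the survey plots pass through three screens before
modeling:

1. pairwise Pearson correlation — while any pair has |r| above the threshold
   (default 0.85), one member is dropped;
2. variance inflation — iteratively remove the predictor with the largest
   VIF until all VIF < 10, where VIF_j = 1 / (1 - R²_j) from regressing
   predictor j on all the others;
3. permutation-importance backward elimination — repeatedly drop the
   predictor with the lowest %IncMSE and refit, stopping at the first
   removal that worsens cross-validated RMSE beyond a relative tolerance.

Every drop is logged in a :class:`SelectionReport` so the selection path is
auditable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import RasterGrid

__all__ = [
    "SelectionReport",
    "predictor_group",
    "extract_at_plots",
    "correlation_filter",
    "vif",
    "vif_filter",
    "backward_elimination",
    "select_predictors",
]

GROUPS = ("climate", "soil", "topography", "anthropogenic")

_TOPO_NAMES = {"elevation", "slope", "aspect", "dem"}


def predictor_group(name: str) -> str:
    """Predictor group from the naming convention of the synthetic stack."""
    lower = name.lower()
    if lower.startswith(("clim", "bio")):
        return "climate"
    if lower.startswith("soil"):
        return "soil"
    if lower in _TOPO_NAMES or lower.startswith(("topo", "slope", "aspect", "elev")):
        return "topography"
    if lower.startswith(("disturbance", "risk", "ad")):
        return "anthropogenic"
    raise ValueError(f"cannot infer a predictor group for {name!r}")


@dataclass
class SelectionReport:
    """Audit trail of the three selection stages."""

    dropped_by_correlation: list[tuple[str, float]] = field(default_factory=list)
    dropped_by_vif: list[tuple[str, float]] = field(default_factory=list)
    elimination_path: list[tuple[str, float]] = field(default_factory=list)
    final_variables: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_by_correlation": [
                {"variable": v, "abs_r": r} for v, r in self.dropped_by_correlation
            ],
            "dropped_by_vif": [{"variable": v, "vif": x} for v, x in self.dropped_by_vif],
            "elimination_path": [
                {"removed": v, "cv_rmse_after": r} for v, r in self.elimination_path
            ],
            "final_variables": list(self.final_variables),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def extract_at_plots(
    stack: Mapping[str, RasterGrid], plots: pd.DataFrame
) -> pd.DataFrame:
    """Predictor matrix at the plot centers (value of the containing cell).

    *plots* needs columns plot_id, x, y. Raises if any plot falls on nodata,
    listing the offending plot ids.
    """
    matrix = pd.DataFrame(index=plots["plot_id"].to_numpy())
    for name in sorted(stack):
        grid = stack[name]
        matrix[name] = [grid.value_at(x, y) for x, y in zip(plots["x"], plots["y"])]
    bad = matrix.index[matrix.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"plots fall on nodata cells: {list(bad[:10])}")
    matrix.index.name = "plot_id"
    return matrix


def correlation_filter(
    X: pd.DataFrame, threshold: float = 0.85, report: SelectionReport | None = None
) -> pd.DataFrame:
    """Drop predictors until all pairwise |Pearson r| <= threshold.

    Of each offending pair, the member with the larger mean absolute
    correlation to all other variables is dropped (alphabetical tie-break).
    Zero-variance columns are dropped first with a warning.
    """
    report = report if report is not None else SelectionReport()
    X = X.copy()
    constant = [c for c in X.columns if X[c].std() == 0]
    if constant:
        warnings.warn(f"dropping zero-variance predictors before correlation: {constant}")
        for c in constant:
            report.dropped_by_correlation.append((c, float("nan")))
        X = X.drop(columns=constant)

    while X.shape[1] >= 2:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = float(corr.values.max())
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.columns[i], corr.columns[j]
        mean_a, mean_b = corr[a].mean(), corr[b].mean()
        if mean_a > mean_b or (mean_a == mean_b and a > b):
            drop = a
        else:
            drop = b
        report.dropped_by_correlation.append((drop, worst))
        X = X.drop(columns=[drop])
    return X


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column via auxiliary least squares.

    VIF_j = 1 / (1 - R²_j) where R²_j comes from regressing column j (with
    intercept) on all other columns. Exact collinearity yields inf.
    """
    out = {}
    arr = X.to_numpy(dtype=float)
    n = arr.shape[0]
    for j, name in enumerate(X.columns):
        y = arr[:, j]
        others = np.delete(arr, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - resid @ resid / ss_tot
        out[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_filter(
    X: pd.DataFrame, threshold: float = 10.0, report: SelectionReport | None = None
) -> pd.DataFrame:
    """Iteratively remove the largest-VIF predictor while it is >= threshold."""
    report = report if report is not None else SelectionReport()
    X = X.copy()
    while X.shape[1] >= 2:
        scores = vif(X)
        if np.isinf(scores).any():
            warnings.warn("exact collinearity detected; removing deterministically")
            # among the collinear set, drop the alphabetically last
            drop = sorted(scores.index[np.isinf(scores)])[-1]
            report.dropped_by_vif.append((drop, float("inf")))
            X = X.drop(columns=[drop])
            continue
        worst = scores.idxmax()
        if scores[worst] < threshold:
            break
        report.dropped_by_vif.append((worst, float(scores[worst])))
        X = X.drop(columns=[worst])
    return X


def backward_elimination(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    settings=None,
    rel_tolerance: float = 0.01,
    report: SelectionReport | None = None,
) -> pd.DataFrame:
    """Backward elimination on out-of-bag permutation importance (%IncMSE).

    Starting from the full set, the lowest-%IncMSE predictor is removed and
    the model refit; the removal stands while cross-validated RMSE does not
    worsen by more than *rel_tolerance* (relative). The first harmful
    removal is undone and elimination stops. The full path of (removed
    variable, CV RMSE after removal) is recorded.
    """
    from .model import ModelSettings, cross_validate_forest, fit_forest, oob_permutation_importance

    report = report if report is not None else SelectionReport()
    settings = settings or ModelSettings(ntree=300)
    y = np.asarray(y, dtype=float)
    X = X.copy()
    if X.shape[1] < 2:
        report.final_variables = list(X.columns)
        return X

    def _cv_rmse(cols: Sequence[str]) -> float:
        metrics = cross_validate_forest(X[list(cols)].to_numpy(), y, settings)
        return metrics["rmse"]

    current = list(X.columns)
    current_rmse = _cv_rmse(current)
    while len(current) > 1:
        forest = fit_forest(X[current].to_numpy(), y, settings)
        imp = oob_permutation_importance(forest, X[current].to_numpy(), y)
        weakest = current[int(np.argmin(imp))]
        candidate = [c for c in current if c != weakest]
        candidate_rmse = _cv_rmse(candidate)
        report.elimination_path.append((weakest, float(candidate_rmse)))
        if candidate_rmse > current_rmse * (1.0 + rel_tolerance):
            report.elimination_path[-1] = (f"(kept) {weakest}", float(candidate_rmse))
            break
        current, current_rmse = candidate, candidate_rmse
    report.final_variables = current
    return X[current]


def select_predictors(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    corr_threshold: float = 0.85,
    vif_threshold: float = 10.0,
    settings=None,
    rel_tolerance: float = 0.01,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Run the full three-stage selection and return (matrix, report)."""
    report = SelectionReport()
    X1 = correlation_filter(X, corr_threshold, report)
    X2 = vif_filter(X1, vif_threshold, report)
    X3 = backward_elimination(X2, y, settings, rel_tolerance, report)
    return X3, report
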