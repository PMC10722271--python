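"""Random-Forest diversity modeling.

Fits one regression forest per diversity index (1000 trees), tunes mtry (the
number of predictors sampled at each split) by 10-fold cross-validated RMSE,
and derives everything the mapping stages need:

* out-of-bag permutation importance (%IncMSE) with the >15% "crucial" flag;
* univariate partial-dependence curves;
* variance partitioning of cross-validated R² into unique and shared
  fractions of the predictor groups (climate, soil, topography,
  anthropogenic) via the subset-model lattice;
* the landscape prediction surface;
* linear bias correction: a forest's predictions regress toward the sample
  mean, so an OLS line ``S_fit = a * S_obs + b`` is fitted on the
  cross-validated predictions and inverted cell-wise,
  ``S_bc = max((S_fit - b) / a, 0)``;
* an uncertainty map: absolute cross-validation residuals interpolated by
  inverse-distance weighting and classified into terciles (Strongly /
  Moderately / Less predictive).

Cross-validation folds are assigned once per fit, stratified over the
response deciles, and controlled by the settings seed, so every reported
metric is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .grids import RasterGrid

try:  # sklearn's own OOB index bookkeeping, with a faithful local fallback
    import inspect

    from sklearn.ensemble._forest import _generate_sample_indices

    _GSI_TAKES_WEIGHT = (
        "sample_weight" in inspect.signature(_generate_sample_indices).parameters
    )

    def _bootstrap_indices(tree_state, n_samples: int) -> np.ndarray:
        if _GSI_TAKES_WEIGHT:
            return _generate_sample_indices(tree_state, n_samples, n_samples, None)
        return _generate_sample_indices(tree_state, n_samples, n_samples)

except ImportError:  # pragma: no cover - exercised only on other versions

    def _bootstrap_indices(tree_state, n_samples: int) -> np.ndarray:
        rng = np.random.RandomState(tree_state)
        return rng.randint(0, n_samples, n_samples)


UNCERTAINTY_LEVELS = ("Strongly predictive", "Moderately predictive", "Less predictive")

__all__ = [
    "ModelSettings",
    "DiversityModelResult",
    "VariancePartition",
    "UncertaintyMap",
    "fit_forest",
    "stratified_folds",
    "cross_validate_forest",
    "fit_tuned_forest",
    "oob_permutation_importance",
    "permutation_importance",
    "partial_dependence",
    "variance_partitioning",
    "predict_surface",
    "fit_bias_line",
    "bias_correct",
    "uncertainty_map",
]


@dataclass
class ModelSettings:
    """Forest and cross-validation configuration."""

    ntree: int = 1000
    mtry_candidates: Sequence[int] | None = None  # None = spread over 1..p
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class DiversityModelResult:
    """A tuned, fitted diversity model and its evaluation artifacts."""

    forest: RandomForestRegressor
    feature_names: list[str]
    mtry: int
    cv_table: pd.DataFrame  # one row per candidate mtry: r2, mae, rmse
    best_three: pd.DataFrame  # the three lowest-RMSE candidates
    cv_predictions: np.ndarray  # out-of-fold predictions at the training plots
    y: np.ndarray
    bias_a: float
    bias_b: float
    settings: ModelSettings
    importance: pd.DataFrame | None = None

    @property
    def cv_metrics(self) -> dict[str, float]:
        row = self.cv_table.set_index("mtry").loc[self.mtry]
        return {"r2": float(row["r2"]), "mae": float(row["mae"]), "rmse": float(row["rmse"])}


def fit_forest(
    X: np.ndarray, y: np.ndarray, settings: ModelSettings, mtry: int | None = None
) -> RandomForestRegressor:
    """Fit a regression forest; mtry defaults to max(1, p // 3)."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    mtry = mtry if mtry is not None else max(1, p // 3)
    forest = RandomForestRegressor(
        n_estimators=settings.ntree,
        max_features=min(mtry, p),
        random_state=settings.seed,
        bootstrap=True,
        n_jobs=1,
    )
    forest.fit(X, np.asarray(y, dtype=float))
    return forest


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels stratified over the response deciles.

    Samples are ordered by response value and dealt into folds round-robin
    after a seeded shuffle within consecutive blocks, so every fold spans
    the response range — stable behaviour at a few hundred observations.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        labels = rng.permutation(n_folds)[: len(block)]
        folds[block] = labels
    return folds


def cross_validate_forest(
    X: np.ndarray,
    y: np.ndarray,
    settings: ModelSettings,
    mtry: int | None = None,
    folds: np.ndarray | None = None,
) -> dict:
    """K-fold CV metrics (pooled out-of-fold R², MAE, RMSE) and predictions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if folds is None:
        folds = stratified_folds(y, settings.cv_folds, settings.seed)
    preds = np.empty_like(y)
    for k in np.unique(folds):
        test = folds == k
        forest = fit_forest(X[~test], y[~test], settings, mtry)
        preds[test] = forest.predict(X[test])
    resid = y - preds
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return {
        "r2": float(r2),
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "predictions": preds,
    }


def _default_candidates(p: int) -> list[int]:
    return sorted(set(np.unique(np.round(np.linspace(1, p, min(p, 5))).astype(int))))


def fit_tuned_forest(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    settings: ModelSettings | None = None,
) -> DiversityModelResult:
    """Tune mtry by CV RMSE, refit the winner on all data, fit the bias line.

    All candidates share one stratified fold assignment so their metrics are
    directly comparable; candidates exceeding the predictor count are
    skipped with a warning. The three lowest-RMSE candidates are recorded
    alongside the full table.
    """
    settings = settings or ModelSettings()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xarr = X.to_numpy(dtype=float)
    else:
        Xarr = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xarr.shape[1])]
    y = np.asarray(y, dtype=float)
    if len(y) != Xarr.shape[0]:
        raise ValueError("X and y disagree on the number of observations")
    if len(y) < 20:
        raise ValueError("need at least 20 observations to tune and cross-validate")

    p = Xarr.shape[1]
    candidates = list(settings.mtry_candidates or _default_candidates(p))
    usable = []
    for m in candidates:
        if m > p:
            warnings.warn(f"mtry candidate {m} exceeds the {p} available predictors; skipped")
        else:
            usable.append(int(m))
    if not usable:
        raise ValueError("no usable mtry candidate (all exceed the predictor count)")

    folds = stratified_folds(y, settings.cv_folds, settings.seed)
    rows, predictions = [], {}
    for m in usable:
        res = cross_validate_forest(Xarr, y, settings, mtry=m, folds=folds)
        predictions[m] = res["predictions"]
        rows.append({"mtry": m, "r2": res["r2"], "mae": res["mae"], "rmse": res["rmse"]})
    cv_table = pd.DataFrame(rows)
    best = int(cv_table.loc[cv_table["rmse"].idxmin(), "mtry"])
    best_three = cv_table.nsmallest(3, "rmse").reset_index(drop=True)

    forest = fit_forest(Xarr, y, settings, mtry=best)
    a, b = fit_bias_line(y, predictions[best])
    result = DiversityModelResult(
        forest=forest,
        feature_names=names,
        mtry=best,
        cv_table=cv_table,
        best_three=best_three,
        cv_predictions=predictions[best],
        y=y,
        bias_a=a,
        bias_b=b,
        settings=settings,
    )
    result.importance = permutation_importance(result, Xarr, y)
    return result


# -- importance ------------------------------------------------------------


def oob_permutation_importance(
    forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray, seed: int | None = None
) -> np.ndarray:
    """%IncMSE per predictor: percent increase in out-of-bag MSE after
    permuting that predictor, averaged over trees."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(forest.random_state if seed is None else seed)
    totals = np.zeros(p)
    counts = np.zeros(p)
    for tree in forest.estimators_:
        sampled = _bootstrap_indices(tree.random_state, n)
        oob = np.setdiff1d(np.arange(n), sampled, assume_unique=False)
        if len(oob) < 2:
            continue
        Xo = X[oob]
        base_mse = np.mean((y[oob] - tree.predict(Xo)) ** 2)
        denom = base_mse if base_mse > 0 else np.var(y[oob])
        if denom == 0:
            continue
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[rng.permutation(len(oob)), j]
            perm_mse = np.mean((y[oob] - tree.predict(Xp)) ** 2)
            totals[j] += 100.0 * (perm_mse - base_mse) / denom
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, totals / np.maximum(counts, 1), 0.0)


def permutation_importance(
    result: DiversityModelResult, X, y, crucial_threshold: float = 15.0
) -> pd.DataFrame:
    """Importance table with the crucial flag (%IncMSE above 15%)."""
    Xarr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    inc = oob_permutation_importance(result.forest, Xarr, np.asarray(y, float))
    table = pd.DataFrame(
        {"predictor": result.feature_names, "inc_mse_pct": inc}
    ).sort_values("inc_mse_pct", ascending=False, ignore_index=True)
    table["crucial"] = table["inc_mse_pct"] > crucial_threshold
    return table


def partial_dependence(
    result: DiversityModelResult, X: pd.DataFrame, predictor: str, grid_size: int = 50
) -> pd.DataFrame:
    """Univariate partial-dependence curve over the predictor's observed range.

    For each grid value the predictor is fixed at that value in every
    training row (all other predictors untouched) and the mean forest
    prediction recorded — the marginal response accounting for the joint
    distribution of the remaining variables.
    """
    if predictor not in result.feature_names:
        raise ValueError(f"predictor {predictor!r} is not in the model")
    Xarr = X[result.feature_names].to_numpy(dtype=float)
    j = result.feature_names.index(predictor)
    lo, hi = Xarr[:, j].min(), Xarr[:, j].max()
    grid = np.linspace(lo, hi, grid_size) if grid_size > 1 else np.array([(lo + hi) / 2])
    means = []
    for v in grid:
        Xg = Xarr.copy()
        Xg[:, j] = v
        means.append(float(result.forest.predict(Xg).mean()))
    return pd.DataFrame({"value": grid, "mean_prediction": means})


# -- variance partitioning -------------------------------------------------


@dataclass
class VariancePartition:
    """Unique/shared explained-variance fractions over predictor groups.

    components maps each nonempty group subset to the fraction of variance
    attributable to exactly that subset's intersection; r2_by_subset holds
    the cross-validated R² of every union model. The components sum to the
    full-model R² by construction; negative components (a known artifact of
    the decomposition) are retained and flagged.
    """

    groups: list[str]
    components: dict[frozenset, float]
    r2_by_subset: dict[frozenset, float]
    full_r2: float
    residual: float
    negative_components: list[frozenset] = field(default_factory=list)

    def report(self, min_fraction: float = 0.01) -> pd.DataFrame:
        """Display view: components above *min_fraction*, largest first."""
        rows = [
            {"groups": " & ".join(sorted(k)), "fraction": v}
            for k, v in self.components.items()
            if v > min_fraction
        ]
        return pd.DataFrame(rows).sort_values("fraction", ascending=False, ignore_index=True)

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "components": {" & ".join(sorted(k)): v for k, v in self.components.items()},
            "r2_by_subset": {" & ".join(sorted(k)): v for k, v in self.r2_by_subset.items()},
            "full_r2": self.full_r2,
            "residual": self.residual,
        }


def variance_partitioning(
    X: pd.DataFrame,
    group_labels: Mapping[str, str],
    y: np.ndarray,
    settings: ModelSettings | None = None,
) -> VariancePartition:
    """Partition cross-validated R² over the predictor groups.

    One forest is cross-validated per nonempty subset of groups (<= 15
    models for four groups). Writing R(A) for the CV R² of the union model
    of subset A, the exactly-shared components c_T solve the coverage system
    R(A) = sum over T intersecting A of c_T, which an exact linear solve
    inverts; the components therefore sum to the full-model R² identically.
    """
    settings = settings or ModelSettings(ntree=300)
    y = np.asarray(y, dtype=float)
    groups = sorted({group_labels[c] for c in X.columns})
    empties = [g for g in set(group_labels.values()) if g not in groups]
    if empties:
        warnings.warn(f"groups with no predictors excluded: {empties}")
    if not groups:
        raise ValueError("no nonempty predictor group")

    members = {g: [c for c in X.columns if group_labels[c] == g] for g in groups}
    subsets = [
        frozenset(c) for r in range(1, len(groups) + 1) for c in combinations(groups, r)
    ]
    folds = stratified_folds(y, settings.cv_folds, settings.seed)
    r2 = {}
    for sub in subsets:
        cols = [c for g in sorted(sub) for c in members[g]]
        res = cross_validate_forest(X[cols].to_numpy(), y, settings, folds=folds)
        r2[sub] = res["r2"]

    # coverage matrix: row per observed subset A, column per component T
    M = np.array(
        [[1.0 if a & t else 0.0 for t in subsets] for a in subsets]
    )
    rhs = np.array([r2[a] for a in subsets])
    c = np.linalg.solve(M, rhs)
    components = dict(zip(subsets, (float(v) for v in c)))
    full = frozenset(groups)
    return VariancePartition(
        groups=groups,
        components=components,
        r2_by_subset=r2,
        full_r2=float(r2[full]),
        residual=float(1.0 - r2[full]),
        negative_components=[t for t, v in components.items() if v < 0],
    )


# -- landscape prediction, bias correction, uncertainty --------------------


def predict_surface(
    result: DiversityModelResult, stack: Mapping[str, RasterGrid]
) -> RasterGrid:
    """Apply the fitted forest to every valid grid cell of the stack."""
    missing = [n for n in result.feature_names if n not in stack]
    if missing:
        raise ValueError(f"stack lacks model predictors: {missing}")
    template = stack[result.feature_names[0]]
    for name in result.feature_names[1:]:
        if not stack[name].aligned_with(template):
            raise ValueError(f"raster {name!r} is not aligned with the stack grid")
    layers = np.stack([stack[n].values for n in result.feature_names], axis=-1)
    flat = layers.reshape(-1, len(result.feature_names))
    valid = np.all(np.isfinite(flat), axis=1)
    out = np.full(flat.shape[0], np.nan)
    if valid.any():
        out[valid] = result.forest.predict(flat[valid])
    return template.copy_with(out.reshape(template.values.shape))


def fit_bias_line(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """OLS fit of predicted on observed: predicted = a * observed + b."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    a, b = np.polyfit(observed, predicted, 1)
    return float(a), float(b)


def bias_correct(result: DiversityModelResult, surface: RasterGrid) -> RasterGrid:
    """Invert the bias line cell-wise: corrected = max((value - b) / a, 0).

    Cells that would go negative are clamped to 0 (kept in the raster so the
    hotspot threshold still sees them); nodata propagates.
    """
    a, b = result.bias_a, result.bias_b
    if abs(a) < 1e-8:
        raise ValueError("degenerate bias calibration: slope a is (near) zero")
    corrected = np.maximum((surface.values - b) / a, 0.0)
    corrected[~surface.valid_mask()] = np.nan
    return surface.copy_with(corrected)


@dataclass
class UncertaintyMap:
    """Interpolated CV-residual surface and its three-level classification."""

    residual_surface: RasterGrid
    classes: RasterGrid  # 1 = Strongly, 2 = Moderately, 3 = Less predictive
    thresholds: tuple[float, float]
    levels: tuple[str, str, str] = UNCERTAINTY_LEVELS


def _idw(
    template: RasterGrid, px: np.ndarray, py: np.ndarray, values: np.ndarray, power: float
) -> np.ndarray:
    xs = template.x_centers()
    ys = template.y_centers()
    out = np.empty((template.nrows, template.ncols))
    chunk = max(1, int(2_000_000 // max(len(px) * template.ncols, 1)))
    for r0 in range(0, template.nrows, chunk):
        yy = ys[r0 : r0 + chunk]
        dx = xs[None, :, None] - px[None, None, :]
        dy = yy[:, None, None] - py[None, None, :]
        d2 = dx * dx + dy * dy
        exact = d2 < 1e-12
        w = 1.0 / np.maximum(d2, 1e-12) ** (power / 2.0)
        w = np.where(exact, 0.0, w)  # exact hits handled by direct lookup below
        hit = exact.any(axis=2)
        denom = w.sum(axis=2)
        denom[denom == 0] = 1.0
        interp = (w * values[None, None, :]).sum(axis=2) / denom
        if hit.any():
            nearest = np.argmax(exact, axis=2)
            interp = np.where(hit, values[nearest], interp)
        out[r0 : r0 + chunk] = interp
    return out


def uncertainty_map(
    result: DiversityModelResult,
    plots: pd.DataFrame,
    template: RasterGrid,
    power: float = 2.0,
) -> UncertaintyMap:
    """Absolute CV residuals interpolated by IDW and classed into terciles.

    Low interpolated residual = "Strongly predictive"; degenerate (constant)
    residual surfaces collapse to a single all-Strongly class.
    """
    if len(plots) < 3:
        raise ValueError("need at least 3 plots to interpolate a residual surface")
    resid = np.abs(result.y - result.cv_predictions)
    surface_vals = _idw(
        template,
        plots["x"].to_numpy(dtype=float),
        plots["y"].to_numpy(dtype=float),
        resid,
        power,
    )
    surface_vals[~template.valid_mask()] = np.nan
    surface = template.copy_with(surface_vals)

    valid = surface.valid_mask()
    vals = surface_vals[valid]
    t1, t2 = np.quantile(vals, [1 / 3, 2 / 3])
    classes = np.full(surface_vals.shape, np.nan)
    if t1 == t2:  # flat surface: everything is in the best class
        classes[valid] = 1.0
    else:
        classes[valid] = np.digitize(surface_vals[valid], [t1, t2]) + 1.0
    return UncertaintyMap(surface, template.copy_with(classes), (float(t1), float(t2)))
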