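"""Synthetic study-system generator.

Emulates the ingredients of a landscape-scale diversity survey so the whole
pipeline is testable without any real rasters or field data:

* spatially autocorrelated climate and soil rasters (Gaussian-smoothed white
  noise, z-standardized), a DEM-like elevation surface, and slope/aspect
  derived from it, all on one 20 m grid;
* point/line/polygon disturbance sources of the five risk-element types;
* a two-tier survey layout: plots on a coarse 1-km grid over the whole
  extent plus a denser 0.5-km grid inside a focal zone (the study design is
  114 coarse + 277 fine = 391 plots);
* plot communities whose species richness and evenness respond to chosen
  covariates with known coefficients, so parameter recovery can be tested.

Everything is driven by one integer seed: the same (config, seed) pair
reproduces every raster, vector, layout and community bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve, gaussian_filter
from shapely.geometry import LineString, Point

from .grids import RasterGrid
from .risk import RiskElement, load_risk_params

__all__ = [
    "LandscapeConfig",
    "GroundTruth",
    "default_config",
    "default_truth",
    "generate_predictor_stack",
    "generate_risk_elements",
    "generate_plot_layout",
    "simulate_communities",
]


@dataclass
class LandscapeConfig:
    """Geometry and field parameters of a synthetic landscape.

    extent is (xmin, ymin, xmax, ymax) in projected meters; width and height
    must be positive multiples of cell_size. correlation_length (meters)
    controls the spatial autocorrelation of the climate/soil fields; 0 gives
    i.i.d. white noise.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 12000.0, 12000.0)
    cell_size: float = 20.0
    correlation_length: float = 800.0
    n_climate: int = 6
    n_soil: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        xmin, ymin, xmax, ymax = self.extent
        w, h = xmax - xmin, ymax - ymin
        if w <= 0 or h <= 0:
            raise ValueError(f"extent must have positive width and height, got {self.extent}")
        for length, axis in ((w, "width"), (h, "height")):
            ratio = length / self.cell_size
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"extent {axis} {length} is not a multiple of cell_size")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be nonnegative")

    @property
    def ncols(self) -> int:
        return round((self.extent[2] - self.extent[0]) / self.cell_size)

    @property
    def nrows(self) -> int:
        return round((self.extent[3] - self.extent[1]) / self.cell_size)

    def blank_grid(self) -> RasterGrid:
        return RasterGrid(
            np.zeros((self.nrows, self.ncols)),
            xll=self.extent[0],
            yll=self.extent[1],
            cell_size=self.cell_size,
        )


@dataclass
class GroundTruth:
    """Known effect structure injected into simulated communities.

    beta_richness acts on log expected richness; beta_evenness acts on the
    logit of the geometric-series dominance ratio (ratio near 1 = even
    community, high Shannon). Coefficient keys must name generated
    predictors. noise_sd is extra lognormal noise on expected richness.
    """

    beta_richness: dict[str, float] = dc_field(default_factory=dict)
    beta_evenness: dict[str, float] = dc_field(default_factory=dict)
    intercept_richness: float = float(np.log(25.0))
    intercept_evenness: float = 2.0
    noise_sd: float = 0.1
    evenness_noise_sd: float = 0.2


def default_config(seed: int = 0) -> LandscapeConfig:
    """The study-scale landscape: 12 km x 12 km at 20 m resolution."""
    return LandscapeConfig(seed=seed)


def default_truth() -> GroundTruth:
    """Two true drivers (one climate, one soil) against a quiet background."""
    return GroundTruth(
        beta_richness={"clim01": 0.45, "soil01": -0.35},
        beta_evenness={"clim01": 0.8},
    )


# -- rasters ---------------------------------------------------------------


def _autocorrelated_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """White noise smoothed to the requested correlation length, then z-scored."""
    noise = rng.standard_normal(shape)
    if sigma_cells > 0:
        noise = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    return (noise - noise.mean()) / noise.std()


# Horn (1981) 3x3 finite-difference stencils for surface gradients.
_HORN_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_HORN_Y = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)


def _slope_aspect(dem: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect (degrees clockwise from north, flat = -1)."""
    dzdx = convolve(dem, _HORN_X, mode="nearest") / (8.0 * cell_size)
    dzdy = convolve(dem, _HORN_Y, mode="nearest") / (8.0 * cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(dzdx, dzdy)) % 360.0  # 0 = north, clockwise
    aspect = np.where(slope == 0, -1.0, aspect)
    return slope, aspect


def generate_predictor_stack(config: LandscapeConfig) -> dict[str, RasterGrid]:
    """Generate all predictor rasters on one aligned grid.

    Returns climate fields ``clim01..``, soil fields ``soil01..``, plus
    ``elevation`` (meters), ``slope`` (degrees) and ``aspect`` (degrees from
    north, -1 on flat cells), all sharing the config grid.
    """
    rng = np.random.default_rng(config.seed)
    template = config.blank_grid()
    shape = template.values.shape
    sigma = config.correlation_length / config.cell_size

    stack: dict[str, RasterGrid] = {}
    for i in range(config.n_climate):
        stack[f"clim{i + 1:02d}"] = template.copy_with(
            _autocorrelated_field(rng, shape, sigma)
        )
    for i in range(config.n_soil):
        stack[f"soil{i + 1:02d}"] = template.copy_with(
            _autocorrelated_field(rng, shape, sigma)
        )

    # DEM: a smoother field rescaled to a plausible montane elevation band
    relief = _autocorrelated_field(rng, shape, max(sigma * 2, 1.0) if sigma > 0 else 0.0)
    dem = 800.0 + 350.0 * relief
    slope, aspect = _slope_aspect(dem, config.cell_size)
    stack["elevation"] = template.copy_with(dem)
    stack["slope"] = template.copy_with(slope)
    stack["aspect"] = template.copy_with(aspect)
    return stack


# -- risk-element vectors --------------------------------------------------


def generate_risk_elements(
    config: LandscapeConfig,
    counts: Mapping[str, int] | None = None,
    params: Mapping[str, Mapping] | None = None,
) -> list[RiskElement]:
    """Random disturbance sources of the five element types.

    villages and factories are points, roads are polylines crossing the
    extent, artificial and economic forests are polygon patches. *counts*
    maps element type to the number generated (default 3 villages, 1
    factory, 2 roads, 2 artificial-forest and 2 economic-forest patches).
    """
    counts = dict(counts or {"village": 3, "factory": 1, "road": 2,
                             "artificial_forest": 2, "economic_forest": 2})
    if any(c < 0 for c in counts.values()):
        raise ValueError("element counts must be nonnegative")
    params = params or load_risk_params()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    xmin, ymin, xmax, ymax = config.extent
    w, h = xmax - xmin, ymax - ymin

    def _point() -> Point:
        return Point(xmin + rng.uniform(0.05, 0.95) * w, ymin + rng.uniform(0.05, 0.95) * h)

    def _road() -> LineString:
        # a jittered polyline crossing the extent west to east
        xs = np.linspace(xmin, xmax, 6)
        y0 = ymin + rng.uniform(0.15, 0.85) * h
        ys = y0 + np.cumsum(rng.normal(0, 0.05 * h, size=6))
        return LineString(np.column_stack([xs, np.clip(ys, ymin, ymax)]))

    def _patch():
        center = _point()
        return center.buffer(rng.uniform(150.0, 500.0), quad_segs=4)

    builders = {
        "village": _point,
        "factory": _point,
        "road": _road,
        "artificial_forest": _patch,
        "economic_forest": _patch,
    }
    elements = []
    for etype, builder in builders.items():
        p = dict(params.get(etype, {}))
        for _ in range(counts.get(etype, 0)):
            elements.append(
                RiskElement(
                    geometry=builder(),
                    element_type=etype,
                    intensity=float(p.get("intensity", 1.0)),
                    max_distance=float(p.get("max_distance", 500.0)),
                    decay=str(p.get("decay", "linear")),
                    decay_exponent=float(p.get("decay_exponent", 1.0)),
                )
            )
    return elements


# -- survey layout ---------------------------------------------------------


def generate_plot_layout(
    config: LandscapeConfig,
    n_coarse: int = 114,
    n_fine: int = 277,
    focal_zone: tuple[float, float, float, float] | None = None,
    plot_side: float = 20.0,
) -> pd.DataFrame:
    """Two-tier survey plot layout.

    Coarse-tier plots sit on the 1-km grid nodes of the extent; fine-tier
    plots sit on a 0.5-km grid inside *focal_zone*, offset by 0.25 km from
    the coarse grid so no two plots ever share a center. Nodes are consumed
    in row-major (south-to-north, west-to-east) order, which keeps the
    layout deterministic.

    Returns a DataFrame with columns plot_id, x, y, tier, plot_side.
    """
    xmin, ymin, xmax, ymax = config.extent
    if focal_zone is None:
        # centered zone covering ~ 3/4 of each axis
        fx, fy = (xmax - xmin) / 8, (ymax - ymin) / 8
        focal_zone = (xmin + fx, ymin + fy, xmax - fx, ymax - fy)
    fz = focal_zone
    if not (xmin <= fz[0] < fz[2] <= xmax and ymin <= fz[1] < fz[3] <= ymax):
        raise ValueError(f"focal zone {fz} must lie inside the extent {config.extent}")

    def _nodes(x0, y0, x1, y1, spacing, offset):
        xs = np.arange(np.ceil((x0 - offset) / spacing) * spacing + offset, x1, spacing)
        ys = np.arange(np.ceil((y0 - offset) / spacing) * spacing + offset, y1, spacing)
        xs = xs[xs > x0]
        ys = ys[ys > y0]
        return [(x, y) for y in ys for x in xs]

    coarse = _nodes(xmin, ymin, xmax, ymax, 1000.0, 0.0)
    fine = _nodes(*fz, 500.0, 250.0)
    for tier, nodes, wanted in (("coarse", coarse, n_coarse), ("fine", fine, n_fine)):
        if wanted > len(nodes):
            raise ValueError(
                f"{tier} grid can host at most {len(nodes)} plots, {wanted} requested"
            )

    records = []
    for i, (x, y) in enumerate(coarse[:n_coarse]):
        records.append(("C%03d" % (i + 1), x, y, "coarse", plot_side))
    for i, (x, y) in enumerate(fine[:n_fine]):
        records.append(("F%03d" % (i + 1), x, y, "fine", plot_side))
    return pd.DataFrame(records, columns=["plot_id", "x", "y", "tier", "plot_side"])


# -- communities -----------------------------------------------------------


def _standardized_covariates(
    layout: pd.DataFrame, stack: Mapping[str, RasterGrid], names: Sequence[str]
) -> np.ndarray:
    cols = []
    for name in names:
        grid = stack[name]
        vals = np.array([grid.value_at(x, y) for x, y in zip(layout["x"], layout["y"])])
        sd = vals.std()
        cols.append((vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals))
    return np.column_stack(cols) if cols else np.zeros((len(layout), 0))


def _truncated_poisson(rng: np.random.Generator, lam: float, lo: int, hi: int) -> int:
    """Poisson draw rejected until it falls in [lo, hi] (capped retries)."""
    for _ in range(1000):
        k = rng.poisson(lam)
        if lo <= k <= hi:
            return int(k)
    return int(np.clip(round(lam), lo, hi))


def simulate_communities(
    layout: pd.DataFrame,
    stack: Mapping[str, RasterGrid],
    truth: GroundTruth,
    species_pool: int = 120,
    seed: int = 0,
    stems_mean: float = 150.0,
) -> pd.DataFrame:
    """Simulate a stem census for every plot in *layout*.

    Expected log-richness is ``intercept + beta_richness . z`` over the
    standardized covariates at the plot cell; realized richness is a Poisson
    draw truncated to [1, species_pool]. Abundances follow a geometric
    series whose dominance ratio is ``logistic(intercept + beta_evenness
    . z)``, so Shannon evenness carries signal too. Every species receives
    at least one stem and plot abundances sum to the drawn stem count.

    Returns a long-format DataFrame: plot_id, species, abundance,
    mean_dbh_cm, x, y. DBH values are generated for realism but drive
    nothing downstream.
    """
    if species_pool < 2:
        raise ValueError("species_pool must be at least 2")
    unknown = (set(truth.beta_richness) | set(truth.beta_evenness)) - set(stack)
    if unknown:
        raise ValueError(f"ground-truth coefficients name unknown predictors: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    r_names = sorted(truth.beta_richness)
    e_names = sorted(truth.beta_evenness)
    zr = _standardized_covariates(layout, stack, r_names)
    ze = _standardized_covariates(layout, stack, e_names)
    br = np.array([truth.beta_richness[n] for n in r_names])
    be = np.array([truth.beta_evenness[n] for n in e_names])

    pool = np.array([f"sp{i + 1:03d}" for i in range(species_pool)])
    rows = []
    for i, plot in layout.reset_index(drop=True).iterrows():
        log_lam = truth.intercept_richness + (zr[i] @ br if br.size else 0.0)
        log_lam += rng.normal(0.0, truth.noise_sd)
        richness = _truncated_poisson(rng, float(np.exp(log_lam)), 1, species_pool)

        eta = truth.intercept_evenness + (ze[i] @ be if be.size else 0.0)
        eta += rng.normal(0.0, truth.evenness_noise_sd)
        ratio = 1.0 / (1.0 + np.exp(-eta))  # dominance ratio k in (0, 1)

        species = rng.choice(pool, size=richness, replace=False)
        n_stems = max(int(rng.poisson(stems_mean)), richness)
        weights = ratio ** np.arange(richness)
        # guarantee abundance >= 1, allocate the rest by the geometric profile
        extra = rng.multinomial(n_stems - richness, weights / weights.sum())
        abundance = 1 + extra
        dbh = np.round(np.exp(rng.normal(1.6, 0.5, size=richness)) + 1.0, 1)
        for sp, ab, d in zip(species, abundance, dbh):
            rows.append((plot["plot_id"], sp, int(ab), float(d), plot["x"], plot["y"]))

    return pd.DataFrame(
        rows, columns=["plot_id", "species", "abundance", "mean_dbh_cm", "x", "y"]
    )
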