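"""Diversity hotspots and gibbon home-range overlay.

A hotspot is a grid cell whose predicted diversity lies in the top 10% of
all valid cells (the 0.90 quantile; ties at the threshold are all included,
so the flagged fraction can slightly exceed 10%).

Home ranges are circular: each family group gets a frequent-use disk of
area 1.49 km² (radius r = sqrt(A/pi) ≈ 688 m) and an infrequent-use disk of
radius 2r (the frequent range plus an equally wide buffer ring). The
overlay reports, per group and tier, how many hotspot cells fall inside the
disk (cell-center containment), their area, and the fraction of the range
they cover.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import RasterGrid

DEFAULT_HOME_RANGE_KM2 = 1.49

__all__ = [
    "HotspotMask",
    "HomeRange",
    "DEFAULT_HOME_RANGE_KM2",
    "identify_hotspots",
    "home_range_radius",
    "build_home_ranges",
    "overlay_hotspots",
]


@dataclass
class HotspotMask:
    """Boolean hotspot raster plus the threshold that produced it."""

    mask: RasterGrid  # 1.0 = hotspot, 0.0 = not, NaN = nodata
    threshold: float
    quantile: float

    def flagged_fraction(self) -> float:
        valid = self.mask.valid_mask()
        return float(np.nansum(self.mask.values) / valid.sum())


@dataclass
class HomeRange:
    """A family group's circular frequent range and its buffered extension."""

    group: str
    center_x: float
    center_y: float
    area_km2: float

    @property
    def frequent_radius(self) -> float:
        return home_range_radius(self.area_km2)

    @property
    def buffer_width(self) -> float:
        return self.frequent_radius

    @property
    def infrequent_radius(self) -> float:
        return self.frequent_radius + self.buffer_width


def identify_hotspots(surface: RasterGrid, q: float = 0.90) -> HotspotMask:
    """Flag cells at or above the *q*-quantile of the valid cell values."""
    valid = surface.valid_mask()
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("cannot identify hotspots on an all-nodata surface")
    if n_valid < 10:
        raise ValueError(f"need at least 10 valid cells, got {n_valid}")
    vals = surface.values[valid]
    threshold = float(np.quantile(vals, q))
    if vals.min() == vals.max():
        warnings.warn("constant surface: every cell ties at the hotspot threshold")
    mask = np.full(surface.values.shape, np.nan)
    mask[valid] = (surface.values[valid] >= threshold).astype(float)
    return HotspotMask(surface.copy_with(mask), threshold, q)


def home_range_radius(area_km2: float) -> float:
    """Radius in meters of a circular range of the given area (km²)."""
    if area_km2 <= 0:
        raise ValueError(f"home-range area must be positive, got {area_km2}")
    return math.sqrt(area_km2 * 1e6 / math.pi)


def build_home_ranges(
    centers: pd.DataFrame, area_km2: float = DEFAULT_HOME_RANGE_KM2
) -> list[HomeRange]:
    """One :class:`HomeRange` per group center.

    *centers* needs columns ``group, x, y``; group ids must be unique.
    """
    if centers["group"].duplicated().any():
        dupes = centers.loc[centers["group"].duplicated(), "group"].tolist()
        raise ValueError(f"duplicate home-range group ids: {dupes}")
    if len(centers) < 1:
        raise ValueError("at least one group center is required")
    return [
        HomeRange(str(row["group"]), float(row["x"]), float(row["y"]), area_km2)
        for _, row in centers.iterrows()
    ]


def overlay_hotspots(
    hotspots: HotspotMask, ranges: Sequence[HomeRange], index_name: str = "diversity"
) -> pd.DataFrame:
    """Hotspot coverage per group and range tier.

    A cell belongs to a range iff its center lies inside the disk. Columns:
    group, tier, index, cells_in_range, hotspot_cells, hotspot_area_m2,
    coverage_fraction. Ranges wholly outside the raster produce zero counts
    with a warning.
    """
    grid = hotspots.mask
    xs = grid.x_centers()
    ys = grid.y_centers()
    xx, yy = np.meshgrid(xs, ys)
    flagged = np.nan_to_num(grid.values, nan=0.0) > 0
    valid = grid.valid_mask()
    cell_area = grid.cell_size**2

    rows = []
    for hr in ranges:
        for tier, radius in (("frequent", hr.frequent_radius), ("infrequent", hr.infrequent_radius)):
            inside = (
                (xx - hr.center_x) ** 2 + (yy - hr.center_y) ** 2 <= radius**2
            ) & valid
            n_in = int(inside.sum())
            if n_in == 0:
                warnings.warn(
                    f"home range {hr.group} ({tier}) lies outside the raster; zero counts"
                )
            n_hot = int((inside & flagged).sum())
            rows.append(
                {
                    "group": hr.group,
                    "tier": tier,
                    "index": index_name,
                    "cells_in_range": n_in,
                    "hotspot_cells": n_hot,
                    "hotspot_area_m2": n_hot * cell_area,
                    "coverage_fraction": n_hot / n_in if n_in else 0.0,
                }
            )
    return pd.DataFrame(rows)


def overlay_to_json(report: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(orient="records"), fh, indent=2)
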