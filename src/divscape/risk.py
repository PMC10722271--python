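"""Environmental Risk Surfaces: anthropogenic disturbance with distance decay.

Each risk element (village, factory, road, artificial forest, economic
forest) carries a base interference intensity that decays with Euclidean
distance, reaching exactly zero at the element's maximum influence distance.
The overall disturbance raster is the sum of all per-element intensities.

Decay kernels
-------------
``linear``    I(d) = I0 * (1 - d/Dmax)          for d < Dmax, else 0
``constant``  I(d) = I0                          for d < Dmax, else 0
``convex``    I(d) = I0 * (1 - d/Dmax)^gamma,    gamma > 1
``concave``   I(d) = I0 * (1 - d/Dmax)^gamma,    gamma < 1

All kernels equal I0 at d = 0 and 0 at d >= Dmax.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import shapely
import yaml
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .grids import RasterGrid

ELEMENT_TYPES = ("village", "factory", "road", "artificial_forest", "economic_forest")
DECAY_KINDS = ("linear", "constant", "convex", "concave")

__all__ = [
    "RiskElement",
    "ELEMENT_TYPES",
    "DECAY_KINDS",
    "decay_intensity",
    "distance_to_element",
    "build_risk_surface",
    "load_risk_params",
    "read_elements_geojson",
    "write_elements_geojson",
]


@dataclass
class RiskElement:
    """A vector disturbance source with an attached decay model."""

    geometry: BaseGeometry
    element_type: str
    intensity: float  # base interference intensity I0 at distance 0
    max_distance: float  # meters beyond which interference is exactly 0
    decay: str = "linear"
    decay_exponent: float = 1.0  # gamma, used by convex/concave kernels

    def __post_init__(self) -> None:
        if self.element_type not in ELEMENT_TYPES:
            raise ValueError(
                f"unknown element type {self.element_type!r}; expected one of {ELEMENT_TYPES}"
            )
        if self.decay not in DECAY_KINDS:
            raise ValueError(f"unknown decay kind {self.decay!r}; expected one of {DECAY_KINDS}")
        if self.intensity < 0:
            raise ValueError("base intensity I0 must be nonnegative")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive meters")
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent gamma must be positive")


def decay_intensity(d, element: RiskElement):
    """Interference intensity of *element* at distance *d* (meters).

    Accepts a scalar or array of nonnegative distances; vectorized.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    i0, dmax = element.intensity, element.max_distance
    frac = 1.0 - np.minimum(d, dmax) / dmax
    if element.decay == "linear":
        out = i0 * frac
    elif element.decay == "constant":
        out = np.where(d < dmax, i0, 0.0)
    else:  # convex (gamma > 1) and concave (gamma < 1) share the power form
        out = i0 * frac**element.decay_exponent
    return float(out) if out.ndim == 0 else out


def distance_to_element(template: RasterGrid, geometry: BaseGeometry) -> RasterGrid:
    """Per-cell Euclidean distance from cell centers to *geometry*.

    Zero inside polygons; shapely's distance is already 0 for contained points.
    """
    if geometry is None or geometry.is_empty:
        raise ValueError("cannot build a distance field for an empty geometry")
    xs = template.x_centers()
    ys = template.y_centers()
    xx, yy = np.meshgrid(xs, ys)
    pts = shapely.points(xx.ravel(), yy.ravel())
    dist = shapely.distance(pts, geometry).reshape(template.values.shape)
    return template.copy_with(dist)


def build_risk_surface(template: RasterGrid, elements: Sequence[RiskElement]) -> RasterGrid:
    """Sum the decayed interference intensities of all elements on *template*.

    Cells that are nodata in the template stay nodata.
    """
    total = np.zeros_like(template.values)
    for element in elements:
        dist = distance_to_element(template, element.geometry)
        total += decay_intensity(dist.values, element)
    total[~template.valid_mask()] = np.nan
    return template.copy_with(total)


# -- parameter defaults and vector I/O ------------------------------------


def load_risk_params(path: str | os.PathLike | None = None) -> dict[str, dict]:
    """Per-element-type decay parameters (I0, Dmax, decay kind).

    With no *path*, the packaged default table is used. Its values are
    placeholders chosen for plausibility, not field-calibrated constants;
    real applications should supply their own YAML.
    """
    if path is None:
        text = resources.files("divscape").joinpath("data/ers_defaults.yml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    params = yaml.safe_load(text)
    unknown = set(params) - set(ELEMENT_TYPES)
    if unknown:
        raise ValueError(f"risk parameter file names unknown element types: {sorted(unknown)}")
    return params


def write_elements_geojson(elements: Iterable[RiskElement], path: str | os.PathLike) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": json.loads(shapely.to_geojson(el.geometry)),
            "properties": {
                "element_type": el.element_type,
                "intensity": el.intensity,
                "max_distance": el.max_distance,
                "decay": el.decay,
                "decay_exponent": el.decay_exponent,
            },
        }
        for el in elements
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_elements_geojson(
    path: str | os.PathLike, params: dict[str, dict] | None = None
) -> list[RiskElement]:
    """Read risk elements; feature properties override *params* defaults."""
    params = params or {}
    with open(path) as fh:
        collection = json.load(fh)
    elements = []
    for feat in collection["features"]:
        props = feat.get("properties", {})
        etype = props["element_type"]
        defaults = params.get(etype, {})
        elements.append(
            RiskElement(
                geometry=shapely_shape(feat["geometry"]),
                element_type=etype,
                intensity=float(props.get("intensity", defaults.get("intensity", 1.0))),
                max_distance=float(props.get("max_distance", defaults.get("max_distance", 500.0))),
                decay=str(props.get("decay", defaults.get("decay", "linear"))),
                decay_exponent=float(
                    props.get("decay_exponent", defaults.get("decay_exponent", 1.0))
                ),
            )
        )
    return elements
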