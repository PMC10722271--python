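"""Georeferenced raster grids and their plain-text I/O.

A :class:`RasterGrid` is the common spatial currency of the pipeline: a 2-D
array of cell values on a regular grid in projected meters, with row 0 at the
top (north). Missing data are held as NaN in memory and written as a nodata
sentinel on disk. Grids are read and written as ESRI ASCII grids (``.asc``),
a widely supported text raster format.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "RasterGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
    "resample_to_template",
]


@dataclass
class RasterGrid:
    """A regular raster in projected coordinates.

    Parameters
    ----------
    values
        2-D float array, shape (nrows, ncols); row 0 is the northernmost row.
        NaN marks nodata.
    xll, yll
        Coordinates (meters) of the lower-left corner of the grid.
    cell_size
        Square cell edge length in meters; must be positive.
    crs
        Optional free-form CRS tag carried through for provenance.
    """

    values: np.ndarray
    xll: float
    yll: float
    cell_size: float
    crs: str | None = None
    nodata: float = field(default=-9999.0, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    # -- geometry ---------------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid footprint."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cell_size,
            self.yll + self.nrows * self.cell_size,
        )

    def x_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Row-center y coordinates, top row first."""
        top = self.yll + self.nrows * self.cell_size
        return top - (np.arange(self.nrows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.xll + (col + 0.5) * self.cell_size,
            self.yll + (self.nrows - row - 0.5) * self.cell_size,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing the point; raises if outside."""
        col = int(math.floor((x - self.xll) / self.cell_size))
        row = int(math.floor((self.yll + self.nrows * self.cell_size - y) / self.cell_size))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({x}, {y}) lies outside the raster extent {self.extent}")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        row, col = self.index_of(x, y)
        return float(self.values[row, col])

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.xll, other.xll, abs_tol=1e-6)
            and math.isclose(self.yll, other.yll, abs_tol=1e-6)
            and math.isclose(self.cell_size, other.cell_size, abs_tol=1e-9)
        )

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        """A new grid on the same georeference carrying different values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must match the grid shape")
        return RasterGrid(values, self.xll, self.yll, self.cell_size, self.crs, self.nodata)

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


# -- I/O -------------------------------------------------------------------


def write_ascii_grid(grid: RasterGrid, path: str | os.PathLike) -> None:
    """Write an ESRI ASCII grid; NaN cells become the nodata sentinel."""
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.xll:.6f}\n"
        f"yllcorner {grid.yll:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {grid.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path: str | os.PathLike) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    grid = RasterGrid(
        values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )
    if grid.values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data block does not match declared nrows/ncols")
    return grid


def write_stack(stack: Mapping[str, RasterGrid], directory: str | os.PathLike) -> None:
    """Write each named raster as ``<name>.asc`` under *directory*."""
    os.makedirs(directory, exist_ok=True)
    for name, grid in stack.items():
        write_ascii_grid(grid, os.path.join(directory, f"{name}.asc"))


def read_stack(directory: str | os.PathLike) -> dict[str, RasterGrid]:
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"raster stack directory not found: {directory}")
    stack: dict[str, RasterGrid] = {}
    for fname in sorted(os.listdir(directory)):
        if fname.endswith(".asc"):
            stack[fname[:-4]] = read_ascii_grid(os.path.join(directory, fname))
    return stack


def _iter_names(stack: Mapping[str, RasterGrid]) -> Iterator[str]:
    return iter(sorted(stack))


# -- resampling ------------------------------------------------------------


def resample_to_template(raster: RasterGrid, template: RasterGrid) -> RasterGrid:
    """Bilinearly resample *raster* onto the grid of *template*.

    Each template cell center is interpolated from the four surrounding
    source cell centers. Template cells whose interpolation footprint falls
    outside the source grid, or touches a nodata source cell, become nodata.
    """
    sx0, sy0, sx1, sy1 = raster.extent
    tx0, ty0, tx1, ty1 = template.extent
    if tx0 >= sx1 or tx1 <= sx0 or ty0 >= sy1 or ty1 <= sy0:
        raise ValueError("raster and template extents are disjoint")

    xs = template.x_centers()
    ys = template.y_centers()
    # fractional index of each template center in source cell-center space
    cols = (xs - (raster.xll + raster.cell_size / 2)) / raster.cell_size
    top = raster.yll + raster.nrows * raster.cell_size
    rows = ((top - raster.cell_size / 2) - ys) / raster.cell_size
    cc, rr = np.meshgrid(cols, rows)
    out = map_coordinates(raster.values, [rr, cc], order=1, mode="constant", cval=np.nan)
    return template.copy_with(out)
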