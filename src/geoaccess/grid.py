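"""Planar raster grids and text-based raster I/O.

All layers in a pipeline share a single :class:`GridSpec`: a regular grid of
square cells in planar meter coordinates, row 0 at the top (``origin_y`` is
the *top-left* corner, so y decreases with increasing row index).  Rasters are
read and written as ESRI ASCII grids, a plain-text format understood by GDAL,
QGIS and ArcGIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "Raster", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular planar raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both at least 1.
    cell_size
        Cell edge length in meters (> 0); cells are square.
    origin_x, origin_y
        Planar coordinates (meters) of the grid's top-left corner.
    nodata_value
        Sentinel used for missing cells on disk.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) in meters."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates of every cell as two (n_rows, n_cols) arrays."""
        cols = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(cols, rows)
        return xx, yy

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) containing planar point (x, y).

        Points exactly on the right/bottom edge are clamped into the last
        row/column so the closed extent maps onto valid indices.
        """
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        if x == self.origin_x + self.n_cols * self.cell_size:
            col = self.n_cols - 1
        if y == self.origin_y - self.n_rows * self.cell_size:
            row = self.n_rows - 1
        return row, col

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.extent
        return x0 <= x <= x1 and y0 <= y <= y1

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid covering the same extent with cells ``factor`` times larger.

        Requires both dimensions to be divisible by ``factor`` (exact nesting).
        """
        if factor < 1 or self.n_rows % factor or self.n_cols % factor:
            raise ValueError(
                f"grid {self.n_rows}x{self.n_cols} does not nest into blocks of {factor}"
            )
        return GridSpec(
            self.n_rows // factor,
            self.n_cols // factor,
            self.cell_size * factor,
            self.origin_x,
            self.origin_y,
            self.nodata_value,
        )

    def same_extent(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return all(abs(a - b) <= tol for a, b in zip(self.extent, other.extent))


@dataclass
class Raster:
    """A 2-D array bound to a :class:`GridSpec`.

    ``values`` uses NaN for nodata and, for travel-time layers, +inf for
    unreachable cells; both are mapped to sentinels on disk.
    """

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"array shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy())


def write_ascii_grid(
    raster: Raster, path: str | Path, *, unreachable_value: float | None = None
) -> None:
    """Write a raster as an ESRI ASCII grid (text).

    NaN cells become the grid's nodata value; +inf cells become
    ``unreachable_value`` if given (travel-time convention: -1), else nodata.
    """
    grid = raster.grid
    vals = raster.values.astype(float).copy()
    inf_sub = grid.nodata_value if unreachable_value is None else unreachable_value
    vals[np.isposinf(vals)] = inf_sub
    vals[np.isnan(vals)] = grid.nodata_value
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, *, unreachable_value: float | None = None) -> Raster:
    """Read an ESRI ASCII grid; inverse of :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        vals = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows,
        n_cols,
        cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        nodata_value=header.get("nodata_value", DEFAULT_NODATA),
    )
    if unreachable_value is not None:
        vals[vals == unreachable_value] = np.inf
    vals[vals == grid.nodata_value] = np.nan
    return Raster(grid, vals)
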