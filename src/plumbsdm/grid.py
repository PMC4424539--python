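"""Gridded raster containers on a single planar kilometre grid.

All spatial data in this package live on one common regular grid: a
:class:`RasterGrid` is a single-band surface (values + NaN nodata mask),
a :class:`SeriesStack` is a per-pixel regular time series of one
environmental signal. Coordinates are planar metres; the grid origin is
the lower-left corner. Raster files are read and written as ESRI ASCII
grids — a plain-text format every GIS understands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NODATA_VALUE = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular planar grid.

    Parameters
    ----------
    nrows, ncols : int
        Grid shape. Row 0 is the *top* row, matching raster convention.
    cell_size : float
        Pixel edge length in metres (default 1000 m, a 1-km grid).
    x_origin, y_origin : float
        Coordinates of the lower-left corner of the grid.
    """

    nrows: int
    ncols: int
    cell_size: float = 1000.0
    x_origin: float = 0.0
    y_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def pixel_index(self, x, y):
        """Row/column of the pixel containing planar point(s) (x, y).

        Containment is half-open floor division — no interpolation. Raises
        ``ValueError`` if any point falls outside the grid extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.y_origin) / self.cell_size).astype(int)
        row = self.nrows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if np.any(bad):
            i = int(np.argmax(np.atleast_1d(bad)))
            xs, ys = np.atleast_1d(x)[i], np.atleast_1d(y)[i]
            raise ValueError(f"point ({xs}, {ys}) falls outside the raster extent")
        return row, col

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every pixel centre, shaped (nrows, ncols)."""
        xs = self.x_origin + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys_bottom_up = self.y_origin + (np.arange(self.nrows) + 0.5) * self.cell_size
        ys = ys_bottom_up[::-1]  # row 0 on top
        return np.meshgrid(xs, ys)


@dataclass
class RasterGrid:
    """A single-band gridded surface; NaN marks nodata."""

    values: np.ndarray
    geometry: GridGeometry
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def sample(self, x, y):
        """Value of the containing pixel for point(s) (x, y) — nearest pixel."""
        row, col = self.geometry.pixel_index(x, y)
        return self.values[row, col]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        return RasterGrid(values, self.geometry, name if name is not None else self.name)

    # -- ESRI ASCII grid I/O ------------------------------------------------

    def write_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (plain text; NaN -> NODATA_value)."""
        out = np.where(np.isnan(self.values), NODATA_VALUE, self.values)
        header = (
            f"ncols {self.geometry.ncols}\n"
            f"nrows {self.geometry.nrows}\n"
            f"xllcorner {self.geometry.x_origin}\n"
            f"yllcorner {self.geometry.y_origin}\n"
            f"cellsize {self.geometry.cell_size}\n"
            f"NODATA_value {NODATA_VALUE}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path, name: str | None = None) -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        geom = GridGeometry(
            nrows=int(header["nrows"]),
            ncols=int(header["ncols"]),
            cell_size=header["cellsize"],
            x_origin=header["xllcorner"],
            y_origin=header["yllcorner"],
        )
        nodata = header.get("nodata_value", NODATA_VALUE)
        values = np.where(values == nodata, np.nan, values)
        if name is None:
            name = str(path)
        return cls(values, geom, name)


@dataclass
class SeriesStack:
    """A per-pixel regular time series of one environmental signal.

    ``values`` has shape (n_timesteps, nrows, ncols); timesteps are evenly
    spaced with ``samples_per_year`` per annual cycle (e.g. 12 for monthly
    composites).
    """

    values: np.ndarray
    geometry: GridGeometry
    samples_per_year: int
    name: str = "signal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SeriesStack values must be 3-d (time, row, col)")
        if self.values.shape[1:] != self.geometry.shape:
            raise ValueError("SeriesStack spatial shape does not match geometry")
        if self.samples_per_year < 4:
            raise ValueError("samples_per_year must be >= 4")

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[0]

    def pixel_series(self, row: int, col: int) -> np.ndarray:
        return self.values[:, row, col]
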