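"""Raster containers and plain-text grid IO shared by all pipeline stages.

The coordinate convention used throughout the package: row 0 is the
northernmost row, and the centre of cell ``(r, c)`` sits at
``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``
where ``origin`` is the outer corner of the top-left cell.

Rasters are serialised as ESRI ASCII grids (``.asc``): a plain-text,
self-describing format whose six-line header carries the geotransform
(``xllcorner``/``yllcorner``/``cellsize``), readable by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

__all__ = [
    "LandCover",
    "NATURAL_VEGETATION",
    "Raster",
    "LandUseRaster",
    "ElevationRaster",
    "read_ascii_grid",
]


class LandCover(IntEnum):
    """The seven land-cover categories of the analysis."""

    CONSTRUCTION = 1
    WATER = 2
    UNUSED = 3
    FARMLAND = 4
    GRASSLAND = 5
    SHRUB = 6
    FOREST = 7


#: Classes extracted as the MSPA foreground (natural vegetation).
NATURAL_VEGETATION = (LandCover.FOREST, LandCover.SHRUB, LandCover.GRASSLAND)

_NODATA = -9999


@dataclass
class Raster:
    """A rectangular single-band grid with square cells.

    Parameters
    ----------
    grid
        2-D array; row 0 is the northernmost row.
    cell_size
        Cell edge length in metres (> 0).
    origin
        ``(x, y)`` map coordinates of the top-left cell corner.
    """

    grid: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (30 m cells -> 0.09 ha)."""
        return self.cell_size**2 / 10_000.0

    @property
    def total_area_ha(self) -> float:
        return self.grid.size * self.cell_area_ha

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def write_ascii(self, path: str | Path, fmt: str = "%.6g") -> None:
        """Write the grid as an ESRI ASCII grid."""
        nrows, ncols = self.grid.shape
        x0, y0 = self.origin
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {x0!r}\n"
            f"yllcorner {y0 - nrows * self.cell_size!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {_NODATA}\n"
        )
        data = np.where(np.isfinite(self.grid.astype(float)), self.grid, _NODATA)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt=fmt)


@dataclass
class LandUseRaster(Raster):
    """Categorical land-cover raster; every cell holds one of the 7 codes."""

    year: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        self.grid = self.grid.astype(np.int16)
        valid = np.isin(self.grid, [int(c) for c in LandCover])
        if not valid.all():
            bad = np.unique(self.grid[~valid])
            raise ValueError(f"invalid land-cover codes present: {bad.tolist()}")

    def class_counts(self) -> dict[LandCover, int]:
        return {c: int(np.count_nonzero(self.grid == c)) for c in LandCover}


@dataclass
class ElevationRaster(Raster):
    """Elevation in metres; finite everywhere."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.grid = self.grid.astype(float)
        if not np.isfinite(self.grid).all():
            raise ValueError("elevation raster contains non-finite values")


@dataclass
class LandscapeBundle:
    """Co-registered land-use series and DEM for one scenario."""

    landuse: list[LandUseRaster]
    dem: ElevationRaster
    years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.years:
            self.years = [lu.year for lu in self.landuse]
        for lu in self.landuse:
            if lu.shape != self.dem.shape:
                raise ValueError(
                    f"land-use shape {lu.shape} does not match DEM shape {self.dem.shape}"
                )


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :meth:`Raster.write_ascii`."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    grid = grid.reshape(nrows, ncols)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    grid = np.where(grid == header.get("nodata_value", _NODATA), np.nan, grid)
    return Raster(grid=grid, cell_size=cell, origin=origin)
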