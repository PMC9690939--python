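"""Comprehensive movement-resistance surface from four weighted factors.

Species movement cost is modelled as a weighted overlay of four
reclassified factor rasters — land-use type, distance to construction
land, slope and elevation — each assigned class resistance values in
[1, 1000]:

    R_final = 0.32 * R_landuse + 0.27 * R_dist_construction
            + 0.22 * R_slope + 0.19 * R_elevation

Because the weights sum to 1 and every class value lies in [1, 1000],
the combined surface is bounded by [1, 853] under the default tables
(the per-factor maxima are 1000, 900, 800 and 600).

Interval classes are closed on their upper bound: a slope of exactly 15
degrees falls in the 0-15 class, an elevation of exactly 100 m in the
"<=100" class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import ElevationRaster, LandCover, LandUseRaster, Raster

__all__ = [
    "FactorTable",
    "ResistanceSurface",
    "DEFAULT_FACTORS",
    "FACTOR_WEIGHTS",
    "slope_from_dem",
    "distance_to_construction",
    "reclassify_factor",
    "combine_resistance",
    "build_resistance_surface",
]

#: Factor weights of the comprehensive overlay (sum to 1.00).
FACTOR_WEIGHTS: dict[str, float] = {
    "land_use": 0.32,
    "dist_construction": 0.27,
    "slope": 0.22,
    "elevation": 0.19,
}


@dataclass
class FactorTable:
    """Reclassification table for one resistance factor.

    ``categories`` maps discrete codes to resistance values;
    ``intervals`` is an ordered list of ``(upper_bound, value)`` pairs,
    each class covering ``(previous_upper, upper]`` with the first class
    closed below at the factor's minimum. Exactly one of the two is used.
    """

    factor: str
    weight: float
    categories: dict[int, float] = field(default_factory=dict)
    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = list(self.categories.values()) + [v for _, v in self.intervals]
        if any(not 1 <= v <= 1000 for v in values):
            raise ValueError(f"{self.factor}: resistance values must lie in [1, 1000]")
        if self.intervals and [b for b, _ in self.intervals] != sorted(
            b for b, _ in self.intervals
        ):
            raise ValueError(f"{self.factor}: interval bounds must be increasing")

    @property
    def max_value(self) -> float:
        return max(list(self.categories.values()) + [v for _, v in self.intervals])


DEFAULT_FACTORS: dict[str, FactorTable] = {
    "land_use": FactorTable(
        "land_use",
        FACTOR_WEIGHTS["land_use"],
        categories={
            int(LandCover.CONSTRUCTION): 1000,
            int(LandCover.WATER): 900,
            int(LandCover.UNUSED): 600,
            int(LandCover.FARMLAND): 500,
            int(LandCover.GRASSLAND): 100,
            int(LandCover.SHRUB): 1,
            int(LandCover.FOREST): 1,
        },
    ),
    "dist_construction": FactorTable(
        "dist_construction",
        FACTOR_WEIGHTS["dist_construction"],
        intervals=[(200, 900), (500, 700), (1000, 500), (2000, 300), (np.inf, 1)],
    ),
    "slope": FactorTable(
        "slope",
        FACTOR_WEIGHTS["slope"],
        intervals=[(15, 1), (30, 200), (45, 400), (np.inf, 800)],
    ),
    "elevation": FactorTable(
        "elevation",
        FACTOR_WEIGHTS["elevation"],
        intervals=[(100, 1), (200, 200), (400, 400), (np.inf, 600)],
    ),
}

#: Bounds of the combined surface under the default tables.
RESISTANCE_MIN = 1.0
RESISTANCE_MAX = sum(
    FACTOR_WEIGHTS[name] * DEFAULT_FACTORS[name].max_value for name in FACTOR_WEIGHTS
)  # = 853.0


@dataclass
class ResistanceSurface:
    """Combined resistance raster with its four factor provenance rasters."""

    grid: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    provenance: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def as_raster(self) -> Raster:
        return Raster(grid=self.grid, cell_size=self.cell_size, origin=self.origin)


def slope_from_dem(dem: ElevationRaster) -> np.ndarray:
    """Per-cell slope in degrees from central differences over cell_size."""
    rows, cols = dem.shape
    if rows < 2:
        raise ValueError("DEM has a single row: slope undefined along the row axis")
    if cols < 2:
        raise ValueError("DEM has a single column: slope undefined along the column axis")
    gy, gx = np.gradient(dem.grid, dem.cell_size)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def distance_to_construction(landuse: LandUseRaster) -> np.ndarray:
    """Euclidean distance (m, cell centres) to the nearest construction cell.

    Zero on construction cells; +inf everywhere when the landscape has no
    construction (so every cell reclassifies into the farthest class).
    """
    construction = landuse.grid == LandCover.CONSTRUCTION
    if not construction.any():
        return np.full(landuse.shape, np.inf)
    return ndimage.distance_transform_edt(~construction, sampling=landuse.cell_size)


def reclassify_factor(raster: np.ndarray, table: FactorTable) -> np.ndarray:
    """Map each cell of ``raster`` to its class's resistance value."""
    raster = np.asarray(raster)
    if table.categories:
        out = np.full(raster.shape, np.nan)
        for code, value in table.categories.items():
            out[raster == code] = value
        if np.isnan(out).any():
            r, c = map(int, np.argwhere(np.isnan(out))[0])
            raise ValueError(
                f"{table.factor}: value {raster[r, c]!r} at cell ({r}, {c}) "
                "is not covered by the factor table"
            )
        return out
    bounds = np.array([b for b, _ in table.intervals])
    values = np.array([v for _, v in table.intervals])
    # classes closed on their upper bound: index of first bound >= value
    idx = np.searchsorted(bounds, raster, side="left")
    if (idx >= len(values)).any():
        r, c = map(int, np.argwhere(idx >= len(values))[0])
        raise ValueError(
            f"{table.factor}: value {raster[r, c]!r} at cell ({r}, {c}) "
            "exceeds the last class bound"
        )
    return values[idx].astype(float)


def combine_resistance(
    factors: dict[str, np.ndarray],
    weights: dict[str, float] | None = None,
    cell_size: float = 30.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ResistanceSurface:
    """Weighted overlay of the four factor resistance rasters."""
    weights = dict(FACTOR_WEIGHTS if weights is None else weights)
    missing = set(weights) - set(factors)
    if missing:
        raise ValueError(f"missing factor rasters: {sorted(missing)}")
    shapes = {name: np.asarray(r).shape for name, r in factors.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"factor rasters are not co-registered: {shapes}")
    grid = sum(weights[name] * np.asarray(factors[name], dtype=float) for name in weights)
    return ResistanceSurface(
        grid=grid, cell_size=cell_size, origin=origin, provenance=dict(factors)
    )


def build_resistance_surface(
    landuse: LandUseRaster,
    dem: ElevationRaster,
    tables: dict[str, FactorTable] | None = None,
) -> ResistanceSurface:
    """End-to-end resistance surface for one land-use raster and its DEM."""
    tables = DEFAULT_FACTORS if tables is None else tables
    if landuse.shape != dem.shape:
        raise ValueError(f"shape mismatch: land use {landuse.shape} vs DEM {dem.shape}")
    factors = {
        "land_use": reclassify_factor(landuse.grid, tables["land_use"]),
        "dist_construction": reclassify_factor(
            distance_to_construction(landuse), tables["dist_construction"]
        ),
        "slope": reclassify_factor(slope_from_dem(dem), tables["slope"]),
        "elevation": reclassify_factor(dem.grid, tables["elevation"]),
    }
    weights = {name: tables[name].weight for name in factors}
    return combine_resistance(
        factors, weights, cell_size=landuse.cell_size, origin=landuse.origin
    )
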