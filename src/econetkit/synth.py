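"""Multi-temporal synthetic landscape generator.

Emulates the statistical structure the downstream analysis assumes without
any real remote-sensing inputs: a smooth correlated terrain, one connected
low-elevation water band, clusters of contiguous natural-vegetation blocks
(forest cores joined by thin shrub corridors), scattered grassland and
unused-land patches, a farmland matrix, and urban cores that grow
monotonically by edge accretion over the year series — mimicking the sharp
construction-land expansion observed in rapidly urbanising coastal
agglomerations.

Everything is deterministic for a fixed :class:`ScenarioConfig.seed`.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import ElevationRaster, LandCover, LandscapeBundle, LandUseRaster

__all__ = [
    "ConfigurationError",
    "GenerationError",
    "ScenarioConfig",
    "generate_dem",
    "generate_landuse_series",
    "generate_bundle",
]


class ConfigurationError(ValueError):
    """Raised for invalid scenario configurations."""


class GenerationError(RuntimeError):
    """Raised when a generation step cannot satisfy its contract."""


# Default vegetation-block layout: per-cluster block areas in hectares.
# The ladder spans the five habitat-area thresholds (10/60/300/500/1000 ha)
# with a margin for erosion loss, so the default scenario yields a strictly
# decreasing ecological-source count across the five dispersal scales.
_DEFAULT_CLUSTER_AREAS_HA: tuple[tuple[float, ...], ...] = (
    (1300.0, 220.0, 50.0),
    (700.0, 150.0),
    (580.0, 120.0),
    (550.0, 40.0, 32.0),
    (380.0, 28.0),
    (360.0,),
)

#: Fraction of the landscape vegetation may occupy before block areas are
#: scaled down to fit.
_MAX_VEG_FRACTION = 0.6


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic multi-temporal landscape.

    Defaults describe a ~9 km x 9 km landscape at 30 m resolution observed
    at four decadal time steps, roughly half-covered by natural vegetation,
    with 1% of the landscape converted to construction land per step.
    """

    shape: tuple[int, int] = (300, 300)
    years: tuple[int, ...] = (1990, 2000, 2010, 2020)
    n_forest_blocks: int = 6
    n_urban_seeds: int = 5
    urban_growth_per_step: float = 0.01
    relief_amplitude: float = 600.0
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    seed: int = 42
    cluster_areas_ha: tuple[tuple[float, ...], ...] | None = None
    n_grass_patches: int = 14
    n_unused_patches: int = 2

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise ConfigurationError(f"grid shape must be positive, got {self.shape}")
        if list(self.years) != sorted(set(self.years)):
            raise ConfigurationError("years must be strictly increasing")
        if not 0.0 <= self.urban_growth_per_step < 1.0:
            raise ConfigurationError("urban_growth_per_step must lie in [0, 1)")
        if self.n_forest_blocks < 0 or self.n_urban_seeds < 0:
            raise ConfigurationError("feature counts must be non-negative")
        if self.relief_amplitude < 0:
            raise ConfigurationError("relief_amplitude must be non-negative")


# ---------------------------------------------------------------------------
# Terrain


def _raw_noise_field(config: ScenarioConfig) -> np.ndarray:
    """Unscaled multi-octave smoothed noise underlying the DEM.

    Exposed separately so the DEM's amplitude scaling can be checked
    against this field directly.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    fieldsum = np.zeros((rows, cols))
    for sigma, amp in ((32.0, 1.0), (16.0, 0.5), (8.0, 0.25), (4.0, 0.125)):
        fieldsum += amp * ndimage.gaussian_filter(rng.standard_normal((rows, cols)), sigma)
    return fieldsum


def generate_dem(config: ScenarioConfig) -> ElevationRaster:
    """Generate a smooth correlated elevation surface.

    The raw noise field is min-max normalised, raised to a fixed power
    (3.5) to give the right-skewed hypsometry of a coastal lowland —
    broad plains with isolated hills — and scaled so elevations span
    exactly ``[0, relief_amplitude]`` metres; ``relief_amplitude = 0``
    yields a constant-zero raster.
    """
    raw = _raw_noise_field(config)
    span = raw.max() - raw.min()
    if config.relief_amplitude == 0 or span == 0:
        grid = np.zeros(config.shape)
    else:
        grid = ((raw - raw.min()) / span) ** 3.5 * config.relief_amplitude
    return ElevationRaster(grid=grid, cell_size=config.cell_size, origin=config.origin)


# ---------------------------------------------------------------------------
# Land-use construction helpers


def _water_band(dem: np.ndarray) -> np.ndarray:
    """One connected low-elevation band crossing the grid west to east.

    Dynamic programming picks the minimum-elevation row trace (moves of at
    most one row per column), which is then dilated to a 3-cell-wide band.
    """
    rows, cols = dem.shape
    cost = np.full((rows, cols), np.inf)
    prev = np.zeros((rows, cols), dtype=np.int32)
    cost[:, 0] = dem[:, 0]
    for c in range(1, cols):
        stacked = np.full((3, rows), np.inf)
        stacked[1] = cost[:, c - 1]
        stacked[0, 1:] = cost[:-1, c - 1]
        stacked[2, :-1] = cost[1:, c - 1]
        best = np.argmin(stacked, axis=0)
        cost[:, c] = stacked[best, np.arange(rows)] + dem[:, c]
        prev[:, c] = np.arange(rows) + best - 1
    mask = np.zeros((rows, cols), dtype=bool)
    r = int(np.argmin(cost[:, -1]))
    for c in range(cols - 1, -1, -1):
        mask[r, c] = True
        r = int(prev[r, c])
    return ndimage.binary_dilation(mask, iterations=1)


def _grow_blob(
    allowed: np.ndarray,
    seed_cell: tuple[int, int],
    n_cells: int,
    rng: np.random.Generator,
    roughness: float = 0.6,
    potential: np.ndarray | None = None,
) -> np.ndarray:
    """Grow a compact connected blob of ``n_cells`` from ``seed_cell``.

    Geodesic best-first growth inside ``allowed``: each frontier cell is
    expanded in order of accumulated distance plus smooth noise (plus an
    optional per-cell ``potential``), producing a roughly round patch
    with a slightly irregular boundary that prefers low-potential ground.
    """
    rows, cols = allowed.shape
    noise = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 2.0) * roughness
    if potential is not None:
        noise = noise + potential
    blob = np.zeros((rows, cols), dtype=bool)
    visited = np.zeros((rows, cols), dtype=bool)
    heap: list[tuple[float, int, int]] = [(0.0, seed_cell[0], seed_cell[1])]
    count = 0
    while heap and count < n_cells:
        d, r, c = heapq.heappop(heap)
        if visited[r, c]:
            continue
        visited[r, c] = True
        blob[r, c] = True
        count += 1
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and allowed[rr, cc] and not visited[rr, cc]:
                heapq.heappush(heap, (d + 1.0 + noise[rr, cc], rr, cc))
    return blob


def _farthest_cell(candidates: np.ndarray, occupied: np.ndarray) -> tuple[int, int]:
    """Candidate cell farthest from every occupied cell (deterministic)."""
    if occupied.any():
        dist = ndimage.distance_transform_edt(~occupied)
    else:
        rows, cols = candidates.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        dist = np.minimum.reduce([rr, rows - 1 - rr, cc, cols - 1 - cc]).astype(float)
        dist = dist.max() - dist  # first seed near a corner margin
    masked = np.where(candidates, dist, -np.inf)
    return tuple(np.unravel_index(int(np.argmax(masked)), masked.shape))  # type: ignore[return-value]


def _line_cells(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """Cells of a digital straight line (Bresenham)."""
    cells = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 > r0 else -1
    sc = 1 if c1 > c0 else -1
    err = dr - dc
    r, c = r0, c0
    while True:
        cells.append((r, c))
        if (r, c) == (r1, c1):
            break
        e2 = 2 * err
        if e2 > -dc:
            err -= dc
            r += sr
        if e2 < dr:
            err += dr
            c += sc
    return cells


def _cluster_layout(config: ScenarioConfig) -> list[tuple[float, ...]]:
    """Per-cluster block areas, scaled to fit the landscape."""
    if config.cluster_areas_ha is not None:
        clusters = [tuple(c) for c in config.cluster_areas_ha]
    else:
        base = list(_DEFAULT_CLUSTER_AREAS_HA)
        clusters = [base[i % len(base)] for i in range(config.n_forest_blocks)]
    total_ha = sum(sum(c) for c in clusters)
    rows, cols = config.shape
    landscape_ha = rows * cols * config.cell_size**2 / 10_000.0
    budget = _MAX_VEG_FRACTION * landscape_ha
    if total_ha > budget and total_ha > 0:
        f = budget / total_ha
        clusters = [tuple(a * f for a in c) for c in clusters]
    return clusters


def _base_landuse(config: ScenarioConfig, dem: ElevationRaster, rng: np.random.Generator) -> np.ndarray:
    rows, cols = config.shape
    cell_ha = config.cell_size**2 / 10_000.0
    grid = np.full((rows, cols), int(LandCover.FARMLAND), dtype=np.int16)

    water = _water_band(dem.grid) if min(rows, cols) >= 8 else np.zeros((rows, cols), bool)
    grid[water] = LandCover.WATER

    veg = np.zeros((rows, cols), dtype=bool)
    water_buffer = ndimage.binary_dilation(water, iterations=2)
    cluster_centers: list[tuple[int, int]] = []
    # remnant vegetation concentrates on valley floors so inter-patch
    # movement crosses mostly gentle low terrain
    relief = float(dem.grid.max() - dem.grid.min())
    if relief > 100:
        lowland = dem.grid <= dem.grid.min() + 100.0
        if not lowland.any():
            lowland = dem.grid <= np.quantile(dem.grid, 0.45)
        terrain_potential = 2.0 * (dem.grid - dem.grid.min()) / relief
    else:
        lowland = np.ones_like(dem.grid, dtype=bool)
        terrain_potential = np.zeros_like(dem.grid)

    for areas in _cluster_layout(config):
        # keep >= 3 cells of matrix between clusters so each stays its own
        # vegetation component
        forbidden = water_buffer | ndimage.binary_dilation(veg, iterations=3)
        candidates = ~forbidden
        candidates[:3, :] = candidates[-3:, :] = False
        candidates[:, :3] = candidates[:, -3:] = False
        if not candidates.any():
            raise GenerationError("vegetation placement: no room left for a cluster")
        cluster_blobs: list[np.ndarray] = []
        cluster_veg = np.zeros((rows, cols), dtype=bool)
        for k, area_ha in enumerate(areas):
            n_cells = max(int(round(area_ha / cell_ha)), 4)
            if k == 0:
                seeds = candidates & lowland if (candidates & lowland).any() else candidates
                seed_cell = _farthest_cell(seeds, veg | water)
                allowed = candidates
            else:
                # secondary blocks sit near the primary, separated by a
                # 2-cell gap that the shrub corridor will span
                # geodesic neighbourhood: secondary blocks stay on the same
                # side of the water band as their primary
                near = ndimage.binary_dilation(cluster_veg, iterations=12, mask=~water)
                gap = ndimage.binary_dilation(cluster_veg, iterations=2)
                allowed = candidates & ~gap
                if (allowed & lowland).any():
                    allowed = allowed & lowland
                seed_region = allowed & near
                if not seed_region.any():
                    seed_region = allowed
                if not seed_region.any():
                    continue
                opts = np.argwhere(seed_region)
                seed_cell = tuple(opts[rng.integers(len(opts))])
            blob = _grow_blob(allowed, seed_cell, n_cells, rng, potential=terrain_potential)
            if not blob.any():
                continue
            cluster_blobs.append(blob)
            cluster_veg |= blob
        veg |= cluster_veg
        for blob in cluster_blobs:
            grid[blob] = LandCover.FOREST
        # thin shrub corridors chain the cluster's blocks together
        centers = [tuple(np.argwhere(b).mean(axis=0).round().astype(int)) for b in cluster_blobs]
        if centers:
            cluster_centers.append(centers[0])
        for (r0, c0), (r1, c1) in zip(centers[:-1], centers[1:]):
            for r, c in _line_cells(r0, c0, r1, c1):
                if grid[r, c] == LandCover.FARMLAND:
                    grid[r, c] = LandCover.SHRUB
                    veg[r, c] = True

    # small grassland patches (below every habitat-area threshold), biased
    # toward the matrix between clusters so they act as stepping stones
    for k in range(config.n_grass_patches):
        forbidden = water_buffer | ndimage.binary_dilation(veg, iterations=3)
        candidates = ~forbidden
        if not candidates.any():
            break
        seed_cell = None
        if len(cluster_centers) >= 2 and k % 3 != 2:
            a, b = rng.choice(len(cluster_centers), size=2, replace=False)
            mid = (
                (cluster_centers[a][0] + cluster_centers[b][0]) // 2
                + int(rng.integers(-4, 5)),
                (cluster_centers[a][1] + cluster_centers[b][1]) // 2
                + int(rng.integers(-4, 5)),
            )
            if 0 <= mid[0] < rows and 0 <= mid[1] < cols and candidates[mid]:
                seed_cell = mid
        if seed_cell is None:
            opts = np.argwhere(candidates)
            seed_cell = tuple(opts[rng.integers(len(opts))])
        blob = _grow_blob(candidates, seed_cell, int(rng.integers(30, 90)), rng)
        grid[blob] = LandCover.GRASSLAND
        veg |= blob

    # a little unused (bare) land in the matrix
    for _ in range(config.n_unused_patches):
        candidates = (grid == LandCover.FARMLAND) & ~ndimage.binary_dilation(veg, iterations=2)
        if not candidates.any():
            break
        opts = np.argwhere(candidates)
        seed_cell = tuple(opts[rng.integers(len(opts))])
        blob = _grow_blob(candidates, seed_cell, int(rng.integers(10, 30)), rng)
        grid[blob] = LandCover.UNUSED

    # urban seeds form one compact agglomeration in the farmland matrix,
    # sited as far as possible from vegetation and water
    occupied = grid != LandCover.FARMLAND
    placed = np.zeros((rows, cols), dtype=bool)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    anchor = None
    for _ in range(config.n_urban_seeds):
        candidates = (grid == LandCover.FARMLAND) & ~ndimage.binary_dilation(placed, iterations=4)
        if anchor is not None:
            near = (rr - anchor[0]) ** 2 + (cc - anchor[1]) ** 2 <= 15**2
            if (candidates & near).any():
                candidates &= near
        if not candidates.any():
            raise GenerationError("urban seeding: no farmland cell available")
        if anchor is None:
            r, c = _farthest_cell(candidates, occupied)
            anchor = (r, c)
        else:
            opts = np.argwhere(candidates)
            r, c = opts[rng.integers(len(opts))]
        disk = ((rr - r) ** 2 + (cc - c) ** 2 <= 4) & (grid == LandCover.FARMLAND)
        grid[disk] = LandCover.CONSTRUCTION
        placed |= disk
    return grid


def _grow_construction(grid: np.ndarray, k: int, rng: np.random.Generator, step: int) -> np.ndarray:
    """Convert exactly ``k`` cells to construction, biased toward existing
    construction edges (probability proportional to inverse distance)."""
    out = grid.copy()
    if k == 0:
        return out
    convertible = (out != LandCover.CONSTRUCTION) & (out != LandCover.WATER)
    n_avail = int(convertible.sum())
    if n_avail < k:
        raise GenerationError(
            f"urban growth step {step}: need {k} convertible cells, only {n_avail} available"
        )
    construction = out == LandCover.CONSTRUCTION
    if construction.any():
        dist = ndimage.distance_transform_edt(~construction)
    else:
        dist = np.ones_like(out, dtype=float)
    # edge-growth sprawl: draw only from a band around the current urban
    # footprint, widening it just enough to supply k cells
    radius = 20.0
    flat = np.flatnonzero(convertible & (dist <= radius))
    while len(flat) < k and radius < max(out.shape) * 2:
        radius *= 1.5
        flat = np.flatnonzero(convertible & (dist <= radius))
    if len(flat) < k:
        flat = np.flatnonzero(convertible)
    weights = 1.0 / dist.ravel()[flat] ** 2
    weights /= weights.sum()
    chosen = rng.choice(flat, size=k, replace=False, p=weights)
    out.ravel()[chosen] = LandCover.CONSTRUCTION
    return out


def generate_landuse_series(
    config: ScenarioConfig, dem: ElevationRaster
) -> list[LandUseRaster]:
    """Generate one land-use raster per year with monotone urban growth.

    Each step after year 0 converts exactly
    ``round(urban_growth_per_step * n_cells)`` non-water cells to
    construction, drawn adjacent-biased around the existing urban mask.
    """
    if dem.shape != tuple(config.shape):
        raise ConfigurationError(
            f"DEM shape {dem.shape} does not match configured shape {config.shape}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    base = _base_landuse(config, dem, rng)
    k = int(round(config.urban_growth_per_step * base.size))
    series = []
    grid = base
    for i, year in enumerate(config.years):
        if i > 0:
            grid = _grow_construction(grid, k, rng, step=i)
        series.append(
            LandUseRaster(
                grid=grid.copy(),
                cell_size=config.cell_size,
                origin=config.origin,
                year=int(year),
            )
        )
    return series


def generate_bundle(config: ScenarioConfig) -> LandscapeBundle:
    """Generate the full co-registered scenario (DEM + land-use series)."""
    dem = generate_dem(config)
    landuse = generate_landuse_series(config, dem)
    return LandscapeBundle(landuse=landuse, dem=dem)
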