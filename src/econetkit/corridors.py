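"""Least-cost ecological corridors over a resistance surface.

Movement is modelled on the 8-connected cell graph: a step from cell ``u``
to neighbour ``v`` costs ``step_length * (R(u) + R(v)) / 2`` with
``step_length = cell_size`` for axial moves and ``cell_size * sqrt(2)``
for diagonal ones, the standard raster cost-distance convention. The
minimum cumulative resistance between two source patches is the cheapest
such path between any pair of their cells (boundary-to-boundary).

A pair of patches enters the network when

* its least-cost path does not cross a cell of any third source patch
  (corridors through an intermediate source are ignored), and
* its least-cost distance does not exceed the dispersal-cost threshold,
  taken as ``max_dispersal_km * 1000 * R_ref`` with ``R_ref = 1`` — the
  cost of traversing the maximum dispersal distance over ideal habitat.

Corridor quality: ``cwd_lcpl`` is the cumulative cost divided by the
geometric path length (1.0 on ideal habitat; larger is worse), and the
corridor width is the area of the least-cost band (cells whose summed
cost distance to the two endpoints stays within a cost budget of the
optimum, default 10%) divided by the path length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .mspa import DispersalScale, SourcePatch
from .resistance import ResistanceSurface

__all__ = [
    "Corridor",
    "EcoNetwork",
    "cost_distance",
    "least_cost_path",
    "build_network",
    "corridor_quality",
    "dispersal_cost_threshold",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class Corridor:
    """A least-cost corridor between two source patches."""

    i: int
    j: int
    path: list[tuple[int, int]]
    cwd: float
    length_m: float
    cwd_lcpl: float
    width_m: float | None = None


@dataclass
class EcoNetwork:
    """Source patches (nodes) and least-cost corridors (edges) for one
    dispersal scale and year."""

    scale: DispersalScale
    year: int
    patches: list[SourcePatch]
    corridors: list[Corridor]
    lcd: np.ndarray  # symmetric least-cost distance matrix, inf if unreachable
    landscape_area_ha: float
    cell_size: float = 30.0

    @property
    def n_nodes(self) -> int:
        return len(self.patches)

    @property
    def n_edges(self) -> int:
        return len(self.corridors)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        index = {p.id: k for k, p in enumerate(self.patches)}
        for p in self.patches:
            g.add_node(p.id, area_ha=p.area_ha)
        for c in self.corridors:
            g.add_edge(
                c.i,
                c.j,
                lcd=float(self.lcd[index[c.i], index[c.j]]),
                cwd=c.cwd,
                length_m=c.length_m,
                cwd_lcpl=c.cwd_lcpl,
                width_m=c.width_m,
            )
        return g


def _grid_graph(grid: np.ndarray, cell_size: float):
    """Sparse 8-neighbour step-cost graph over the resistance grid."""
    rows, cols = grid.shape
    idx = np.arange(rows * cols).reshape(rows, cols)
    r = grid.astype(float)
    us, vs, ws = [], [], []
    for (dr, dc), step in (
        ((0, 1), cell_size),
        ((1, 0), cell_size),
        ((1, 1), cell_size * _SQRT2),
        ((1, -1), cell_size * _SQRT2),
    ):
        src = idx[max(0, -dr) : rows - max(0, dr), max(0, -dc) : cols - max(0, dc)]
        dst = idx[max(0, dr) : rows + min(0, dr), max(0, dc) : cols + min(0, dc)]
        cost = step * (r.ravel()[src.ravel()] + r.ravel()[dst.ravel()]) / 2.0
        us.append(src.ravel())
        vs.append(dst.ravel())
        ws.append(cost)
    u = np.concatenate(us)
    v = np.concatenate(vs)
    w = np.concatenate(ws)
    return coo_matrix((w, (u, v)), shape=(rows * cols, rows * cols)).tocsr()


def cost_distance(
    resistance: ResistanceSurface, source: SourcePatch | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Minimal accumulated cost from any source cell to every cell.

    Returns ``(cost, predecessors)`` as flat arrays reshaped to the grid
    (cost) and flat predecessor indices (-9999 at sources).
    """
    rows, cols = resistance.shape
    if isinstance(source, SourcePatch):
        cells = np.array(sorted(source.cells))
    else:
        cells = np.argwhere(np.asarray(source, dtype=bool))
    if len(cells) == 0:
        raise ValueError("source has no cells")
    if (cells < 0).any() or (cells[:, 0] >= rows).any() or (cells[:, 1] >= cols).any():
        raise ValueError("source cells fall outside the raster")
    graph = _grid_graph(resistance.grid, resistance.cell_size)
    flat = cells[:, 0] * cols + cells[:, 1]
    dist, pred, _ = dijkstra(
        graph, directed=False, indices=flat, return_predecessors=True, min_only=True
    )
    return dist.reshape(rows, cols), pred


def _traceback(pred: np.ndarray, end_flat: int, cols: int) -> list[tuple[int, int]]:
    path = [end_flat]
    node = end_flat
    while pred[node] >= 0:
        node = int(pred[node])
        path.append(node)
    path.reverse()
    return [(p // cols, p % cols) for p in path]


def _path_length_m(path: list[tuple[int, int]], cell_size: float) -> float:
    length = 0.0
    for (r0, c0), (r1, c1) in itertools.pairwise(path):
        length += cell_size * (_SQRT2 if (r0 != r1 and c0 != c1) else 1.0)
    return length


def least_cost_path(
    resistance: ResistanceSurface,
    a: SourcePatch,
    b: SourcePatch,
    cost_from_a: tuple[np.ndarray, np.ndarray] | None = None,
) -> Corridor | None:
    """Cheapest corridor between two patches, or None when unreachable.

    The search always runs from the lower-id patch so the corridor (and
    its cost) is identical whichever argument order is used; equal-cost
    meeting cells are broken toward the smallest flat cell index.
    """
    if a.id == b.id or a.cells == b.cells:
        raise ValueError("least-cost path requires two distinct patches")
    if b.id < a.id:
        a, b = b, a
        cost_from_a = None
    rows, cols = resistance.shape
    if cost_from_a is None:
        cost_from_a = cost_distance(resistance, a)
    dist, pred = cost_from_a
    b_flat = np.array(sorted(r * cols + c for r, c in b.cells))
    costs = dist.reshape(-1)[b_flat]
    k = int(np.argmin(costs))
    cwd = float(costs[k])
    if not np.isfinite(cwd):
        return None
    path = _traceback(pred, int(b_flat[k]), cols)
    length = _path_length_m(path, resistance.cell_size)
    if length == 0:
        raise ValueError("zero-length corridor between overlapping patches")
    return Corridor(
        i=a.id, j=b.id, path=path, cwd=cwd, length_m=length, cwd_lcpl=cwd / length
    )


def corridor_quality(
    corridor: Corridor,
    cost_from_i: np.ndarray,
    cost_from_j: np.ndarray,
    cell_size: float,
    band_cost_budget: float | None = None,
) -> tuple[float, float]:
    """Corridor quality ratio and band width.

    ``band_cost_budget`` defaults to 10% of the corridor's cumulative
    cost; the corridor band contains every cell whose cost distances to
    the two endpoint patches sum to at most ``cwd + budget``.
    """
    if len(corridor.path) < 2:
        raise ValueError("corridor must span at least two cells")
    if band_cost_budget is None:
        band_cost_budget = 0.1 * corridor.cwd
    band = (cost_from_i + cost_from_j) <= corridor.cwd + band_cost_budget
    width_m = float(band.sum()) * cell_size**2 / corridor.length_m
    return corridor.cwd_lcpl, width_m


def dispersal_cost_threshold(scale: DispersalScale, r_ref: float = 1.0) -> float:
    """Dispersal gate in cost units: the cost of covering the scale's
    maximum dispersal distance over ideal habitat (R = r_ref)."""
    return scale.max_dispersal_km * 1000.0 * r_ref


def build_network(
    patches: list[SourcePatch],
    resistance: ResistanceSurface,
    scale: DispersalScale,
    year: int = 0,
    topology: str = "complete",
    cost_threshold: float | None = None,
    band_budget_frac: float = 0.1,
    compute_widths: bool = True,
) -> EcoNetwork:
    """Assemble the ecological network for one scale and year.

    Candidate pairs are all unordered patch pairs (``topology="complete"``,
    the default) or the Delaunay edges of patch centroids
    (``topology="planar"``). A candidate is kept iff its least-cost path
    avoids every third patch and its cost distance passes the dispersal
    gate (``cost_threshold``, defaulting to the scale's).
    """
    if topology not in ("complete", "planar"):
        raise ValueError(f"unknown candidate topology {topology!r}")
    if cost_threshold is None:
        cost_threshold = dispersal_cost_threshold(scale)
    rows, cols = resistance.shape
    n = len(patches)
    area_ha = rows * cols * resistance.cell_size**2 / 10_000.0
    if n == 0:
        return EcoNetwork(scale, year, [], [], np.zeros((0, 0)), area_ha, resistance.cell_size)

    patch_of_cell = np.full(rows * cols, -1, dtype=np.int32)
    for k, p in enumerate(patches):
        for r, c in p.cells:
            patch_of_cell[r * cols + c] = k

    cost_maps = [cost_distance(resistance, p) for p in patches]
    flat_cells = [np.array(sorted(r * cols + c for r, c in p.cells)) for p in patches]

    lcd = np.full((n, n), np.inf)
    np.fill_diagonal(lcd, 0.0)
    for i in range(n):
        dist_i = cost_maps[i][0].reshape(-1)
        for j in range(i + 1, n):
            lcd[i, j] = dist_i[flat_cells[j]].min()
    # enforce exact symmetry against floating accumulation-order effects
    for i in range(n):
        for j in range(i + 1, n):
            lcd[j, i] = lcd[i, j]

    if topology == "planar" and n >= 4:
        from scipy.spatial import Delaunay, QhullError

        centroids = np.array(
            [np.mean(np.array(sorted(p.cells)), axis=0) for p in patches]
        )
        try:
            tri = Delaunay(centroids)
            candidates = set()
            for simplex in tri.simplices:
                for u, v in itertools.combinations(sorted(simplex), 2):
                    candidates.add((int(u), int(v)))
            pairs = sorted(candidates)
        except QhullError:
            pairs = list(itertools.combinations(range(n), 2))
    else:
        pairs = list(itertools.combinations(range(n), 2))

    corridors: list[Corridor] = []
    for i, j in pairs:
        if not np.isfinite(lcd[i, j]) or lcd[i, j] > cost_threshold:
            continue
        corridor = least_cost_path(
            resistance, patches[i], patches[j], cost_from_a=cost_maps[i]
        )
        if corridor is None:
            continue
        # intermediate-source exclusion: drop paths crossing a third patch
        crossed = {
            int(patch_of_cell[r * cols + c])
            for r, c in corridor.path
            if patch_of_cell[r * cols + c] >= 0
        }
        if crossed - {i, j}:
            continue
        if compute_widths:
            corridor.cwd_lcpl, corridor.width_m = corridor_quality(
                corridor,
                cost_maps[i][0],
                cost_maps[j][0],
                resistance.cell_size,
                band_cost_budget=band_budget_frac * corridor.cwd,
            )
        corridors.append(corridor)

    return EcoNetwork(
        scale=scale,
        year=year,
        patches=patches,
        corridors=corridors,
        lcd=lcd,
        landscape_area_ha=area_ha,
        cell_size=resistance.cell_size,
    )
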