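"""Independent oracles and fixture builders shared across the test suite.

Everything here is deliberately implemented from first principles
(pure-Python heaps, exhaustive enumeration) so it exercises none of the
code paths it checks.
"""

from __future__ import annotations

import heapq
import itertools
import math

import numpy as np

from econetkit.corridors import Corridor, EcoNetwork
from econetkit.mspa import DISPERSAL_SCALES, SourcePatch

_SQRT2 = math.sqrt(2.0)


def dijkstra_oracle(resistance: np.ndarray, cell_size: float, sources) -> np.ndarray:
    """Brute-force single-heap Dijkstra over the 8-connected cell graph
    with average-resistance step costs."""
    rows, cols = resistance.shape
    dist = np.full((rows, cols), np.inf)
    heap = []
    for r, c in sources:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                step = cell_size * (_SQRT2 if dr and dc else 1.0)
                nd = d + step * (resistance[r, c] + resistance[rr, cc]) / 2.0
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
                    heapq.heappush(heap, (nd, rr, cc))
    return dist


def erosion_oracle(mask: np.ndarray) -> np.ndarray:
    """8-neighbourhood binary erosion by one cell via explicit shifts."""
    padded = np.pad(mask, 1, constant_values=False)
    out = np.ones_like(mask, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out &= padded[1 + dr : 1 + dr + mask.shape[0], 1 + dc : 1 + dc + mask.shape[1]]
    return out & mask


def all_partitions(items: list):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def make_network(
    areas: dict[int, float],
    edges: list[tuple[int, int, float]],
    landscape_area_ha: float = 1000.0,
    scale=DISPERSAL_SCALES["small"],
    year: int = 0,
) -> EcoNetwork:
    """Fabricate an abstract EcoNetwork from node areas and (i, j, lcd)
    edges, bypassing the raster stages."""
    ids = sorted(areas)
    idx = {pid: k for k, pid in enumerate(ids)}
    patches = [
        SourcePatch(id=pid, cells=frozenset({(idx[pid], 0)}), area_ha=areas[pid])
        for pid in ids
    ]
    lcd = np.full((len(ids), len(ids)), np.inf)
    np.fill_diagonal(lcd, 0.0)
    corridors = []
    for i, j, d in edges:
        lcd[idx[i], idx[j]] = lcd[idx[j], idx[i]] = d
        length = max(d, 1.0)
        corridors.append(
            Corridor(
                i=min(i, j),
                j=max(i, j),
                path=[(idx[i], 0), (idx[j], 0)],
                cwd=d,
                length_m=length,
                cwd_lcpl=d / length,
            )
        )
    return EcoNetwork(
        scale=scale,
        year=year,
        patches=patches,
        corridors=corridors,
        lcd=lcd,
        landscape_area_ha=landscape_area_ha,
    )


def max_product_paths(nodes, edges: dict[tuple[int, int], float], rate: float):
    """Exhaustive simple-path search: for every unordered pair, the
    maximum-product movement probability and the argmax path.

    ``edges`` maps unordered (i, j) to lcd. Returns
    {(j, k): (p_star, path)} with p_star = 0 for unreachable pairs.
    """
    adj: dict[int, list[int]] = {v: [] for v in nodes}
    for (i, j) in edges:
        adj[i].append(j)
        adj[j].append(i)

    def edge_lcd(a, b):
        return edges.get((a, b), edges.get((b, a)))

    results = {}
    for j, k in itertools.combinations(sorted(nodes), 2):
        best_cost, best_path = None, None
        stack = [(j, [j], 0.0)]
        while stack:
            node, path, cost = stack.pop()
            if node == k:
                if best_cost is None or cost < best_cost:
                    best_cost, best_path = cost, path
                continue
            for nxt in adj[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt], cost + edge_lcd(node, nxt)))
        if best_cost is None:
            results[(j, k)] = (0.0, None)
        else:
            results[(j, k)] = (math.exp(-rate * best_cost), best_path)
    return results


def pc_oracle(areas: dict[int, float], edges, rate: float, area_total: float) -> float:
    """Probability of connectivity by exhaustive path enumeration."""
    paths = max_product_paths(sorted(areas), edges, rate)
    total = sum(a * a for a in areas.values())  # self terms, p* = 1
    for (j, k), (p_star, _) in paths.items():
        total += 2.0 * areas[j] * areas[k] * p_star
    return total / area_total**2


def bcpc_oracle(areas: dict[int, float], edges, rate: float) -> dict[int, float]:
    """Area-weighted betweenness by exhaustive path enumeration."""
    scores = {v: 0.0 for v in areas}
    for (j, k), (p_star, path) in max_product_paths(sorted(areas), edges, rate).items():
        if path is None:
            continue
        w = areas[j] * areas[k] * p_star
        for interior in path[1:-1]:
            scores[interior] += w
    return scores
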