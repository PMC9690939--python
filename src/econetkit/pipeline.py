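"""End-to-end multi-scale, multi-year orchestration and report writing.

Pipeline order per year: natural-vegetation foreground -> MSPA
classification -> per-scale source extraction -> resistance surface ->
least-cost corridor network -> connectivity indices -> ecological groups;
then, per consecutive year pair and scale, core-node evolution tracking
and life-cycle event classification.

All tabular outputs are CSV with fixed column sets; rasters are ESRI
ASCII grids; corridors are GeoJSON line features; networks are GraphML.
A run manifest records the package version, seed and a configuration
hash so a rerun with identical settings is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .connectivity import ConnectivityReport, DistanceDecay, connectivity_report
from .corridors import EcoNetwork, build_network
from .grids import ElevationRaster, LandUseRaster, read_ascii_grid
from .groups import (
    EvolutionEvent,
    GroupPartition,
    build_weighted_graph,
    classify_events,
    core_nodes,
    greedy_modularity,
    is_core,
    match_patches,
    node_importance,
    track_evolution,
)
from .mspa import (
    DISPERSAL_SCALES,
    binarize_foreground,
    class_proportions,
    classify_mspa,
    extract_sources,
)
from .resistance import build_resistance_surface
from .synth import ScenarioConfig, generate_bundle

logger = logging.getLogger("econetkit")

__all__ = ["RunConfig", "RunResult", "run_multiscale", "parse_config_file"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    scenario: ScenarioConfig | None = None
    landuse_paths: dict[int, str] = field(default_factory=dict)
    dem_path: str | None = None
    scales: tuple[str, ...] = tuple(DISPERSAL_SCALES)
    edge_width_cells: int = 1
    connectivity: int = 8
    decay_p: float = 0.05
    tau: float = 0.2
    topology: str = "complete"
    out_dir: str = "econetkit_out"
    seed: int = 0
    write_rasters: bool = True

    def __post_init__(self) -> None:
        if not self.scales:
            raise ValueError("at least one dispersal scale is required")
        unknown = set(self.scales) - set(DISPERSAL_SCALES)
        if unknown:
            raise ValueError(f"unknown scales: {sorted(unknown)}")


@dataclass
class ScaleYearResult:
    network: EcoNetwork
    report: ConnectivityReport
    partition: GroupPartition
    pni: dict[int, float]
    cores: dict[int, bool]


@dataclass
class RunResult:
    config: RunConfig
    years: list[int]
    per_scale_year: dict[tuple[str, int], ScaleYearResult]
    events: dict[tuple[str, int, int], list[EvolutionEvent]]
    out_dir: Path


def parse_config_file(path: str | Path) -> dict[str, str]:
    """Read a plain-text ``key = value`` configuration / manifest file."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def _load_inputs(config: RunConfig) -> tuple[list[LandUseRaster], ElevationRaster]:
    if config.scenario is not None:
        bundle = generate_bundle(config.scenario)
        return bundle.landuse, bundle.dem
    if not config.landuse_paths or config.dem_path is None:
        raise ValueError("either a scenario or land-use/DEM paths must be provided")
    dem_r = read_ascii_grid(config.dem_path)
    dem = ElevationRaster(grid=dem_r.grid, cell_size=dem_r.cell_size, origin=dem_r.origin)
    series = []
    for year in sorted(config.landuse_paths):
        path = Path(config.landuse_paths[year])
        if not path.exists():
            raise FileNotFoundError(f"missing land-use raster for year {year}: {path}")
        r = read_ascii_grid(path)
        if r.grid.shape != dem.grid.shape:
            raise ValueError(
                f"year {year}: land-use shape {r.grid.shape} != DEM shape {dem.grid.shape}"
            )
        series.append(
            LandUseRaster(grid=r.grid.astype(int), cell_size=r.cell_size, origin=r.origin, year=year)
        )
    return series, dem


def _corridor_geojson(network: EcoNetwork) -> dict:
    from shapely.geometry import LineString, mapping

    cell = network.cell_size
    features = []
    index = {p.id: k for k, p in enumerate(network.patches)}
    for c in network.corridors:
        coords = [((col + 0.5) * cell, -(row + 0.5) * cell) for row, col in c.path]
        geom = LineString(coords) if len(coords) > 1 else None
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom) if geom else None,
                "properties": {
                    "i": c.i,
                    "j": c.j,
                    "lcd": float(network.lcd[index[c.i], index[c.j]]),
                    "cwd": c.cwd,
                    "length_m": c.length_m,
                    "cwd_lcpl": c.cwd_lcpl,
                    "width_m": c.width_m,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def _analyse_scale_year(
    landuse: LandUseRaster,
    sources,
    surface,
    scale_name: str,
    config: RunConfig,
) -> ScaleYearResult:
    scale = DISPERSAL_SCALES[scale_name]
    network = build_network(
        sources, surface, scale, year=landuse.year, topology=config.topology
    )
    decay = DistanceDecay.for_scale_km(scale.max_dispersal_km, p=config.decay_p)
    report = connectivity_report(network, decay)
    wgraph = build_weighted_graph(network, decay)
    if network.n_nodes:
        partition = greedy_modularity(wgraph, year=landuse.year)
    else:
        partition = GroupPartition(year=landuse.year, assignment={}, q=None)
    importances = node_importance(report, network.patches)
    pni = {pid: imp.pni for pid, imp in importances.items()}
    cores = is_core(core_nodes(wgraph, pni)) if pni else {}
    logger.info(
        "scale=%s year=%s V=%d L=%d groups=%d cores=%d",
        scale_name,
        landuse.year,
        network.n_nodes,
        network.n_edges,
        partition.n_groups,
        sum(cores.values()),
    )
    return ScaleYearResult(network, report, partition, pni, cores)


def run_multiscale(config: RunConfig) -> RunResult:
    """Run the full analysis and write all artifacts under ``out_dir``."""
    landuse_series, dem = _load_inputs(config)
    years = [lu.year for lu in landuse_series]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.write_rasters:
        dem_raster = dem
        dem_raster.write_ascii(out / "dem.asc", fmt="%.3f")

    results: dict[tuple[str, int], ScaleYearResult] = {}
    sources_by: dict[tuple[str, int], list] = {}
    proportions = []
    summary_rows = []
    partition_rows = []

    for lu in landuse_series:
        if config.write_rasters:
            lu.write_ascii(out / f"landuse_{lu.year}.asc", fmt="%d")
        mask = binarize_foreground(lu)
        mspa_map = classify_mspa(
            mask, config.edge_width_cells, config.connectivity, cell_size=lu.cell_size
        )
        if config.write_rasters:
            from .grids import Raster

            Raster(
                grid=mspa_map.grid, cell_size=lu.cell_size, origin=lu.origin
            ).write_ascii(out / f"mspa_{lu.year}.asc", fmt="%d")
        props = class_proportions(mspa_map)
        props.insert(0, "year", lu.year)
        proportions.append(props)
        surface = build_resistance_surface(lu, dem)
        if config.write_rasters:
            surface.as_raster().write_ascii(out / f"resistance_{lu.year}.asc", fmt="%.2f")

        for scale_name in config.scales:
            scale = DISPERSAL_SCALES[scale_name]
            sources = extract_sources(mspa_map, scale)
            sources_by[(scale_name, lu.year)] = sources
            res = _analyse_scale_year(lu, sources, surface, scale_name, config)
            results[(scale_name, lu.year)] = res
            summary_rows.append(res.report.network_row().iloc[0].to_dict())

            node_tab = res.report.node_table(res.network)
            node_tab["pni"] = node_tab["id"].map(res.pni)
            node_tab["group_id"] = node_tab["id"].map(res.partition.assignment)
            node_tab["is_core"] = node_tab["id"].map(res.cores).astype("boolean")
            node_tab.to_csv(out / f"nodes_{scale_name}_{lu.year}.csv", index=False)
            for _, row in node_tab.iterrows():
                partition_rows.append(
                    {
                        "patch_id": int(row["id"]),
                        "year": lu.year,
                        "scale": scale_name,
                        "group_id": row["group_id"],
                        "pni": row["pni"],
                        "is_core": row["is_core"],
                    }
                )

            index = {p.id: k for k, p in enumerate(res.network.patches)}
            edge_tab = pd.DataFrame(
                [
                    {
                        "i": c.i,
                        "j": c.j,
                        "lcd": float(res.network.lcd[index[c.i], index[c.j]]),
                        "cwd": c.cwd,
                        "length_m": c.length_m,
                        "cwd_lcpl": c.cwd_lcpl,
                        "width_m": c.width_m,
                    }
                    for c in res.network.corridors
                ],
                columns=["i", "j", "lcd", "cwd", "length_m", "cwd_lcpl", "width_m"],
            )
            edge_tab.to_csv(out / f"edges_{scale_name}_{lu.year}.csv", index=False)

            with open(out / f"corridors_{scale_name}_{lu.year}.geojson", "w") as fh:
                json.dump(_corridor_geojson(res.network), fh, sort_keys=True)
            import networkx as nx

            g = res.network.to_networkx()
            for node, gid in res.partition.assignment.items():
                g.nodes[node]["group_id"] = gid
            nx.write_graphml(g, out / f"network_{scale_name}_{lu.year}.graphml")

    pd.concat(proportions, ignore_index=True).to_csv(
        out / "mspa_proportions.csv", index=False
    )
    pd.DataFrame(
        summary_rows, columns=["scale", "year", "V", "L", "alpha", "beta", "gamma", "pc"]
    ).to_csv(out / "network_summary.csv", index=False)
    pd.DataFrame(
        partition_rows,
        columns=["patch_id", "year", "scale", "group_id", "pni", "is_core"],
    ).to_csv(out / "partitions.csv", index=False)

    # evolution tracking needs at least two years
    events: dict[tuple[str, int, int], list[EvolutionEvent]] = {}
    event_rows = []
    for scale_name in config.scales:
        for y0, y1 in zip(years[:-1], years[1:]):
            res0 = results[(scale_name, y0)]
            res1 = results[(scale_name, y1)]
            identity = match_patches(
                sources_by[(scale_name, y0)], sources_by[(scale_name, y1)]
            )
            relation = track_evolution(
                res0.partition, res0.cores, res1.partition, identity
            )
            evs = classify_events(
                relation, res0.partition, res1.partition, identity, tau=config.tau
            )
            events[(scale_name, y0, y1)] = evs
            for ev in evs:
                event_rows.append(
                    {
                        "year_t": y0,
                        "year_t1": y1,
                        "scale": scale_name,
                        "type": ev.type,
                        "groups_t": ";".join(map(str, sorted(ev.groups_t))),
                        "groups_t1": ";".join(map(str, sorted(ev.groups_t1))),
                    }
                )
    pd.DataFrame(
        event_rows, columns=["year_t", "year_t1", "scale", "type", "groups_t", "groups_t1"]
    ).to_csv(out / "events.csv", index=False)

    config_hash = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    manifest = (
        f"package = econetkit {__version__}\n"
        f"seed = {config.seed}\n"
        f"config_hash = {config_hash}\n"
        f"years = {','.join(map(str, years))}\n"
        f"scales = {','.join(config.scales)}\n"
    )
    (out / "manifest.txt").write_text(manifest)

    return RunResult(config, years, results, events, out)
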