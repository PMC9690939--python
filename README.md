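# econetkit

Multi-scale ecological-network connectivity analysis for fragmented
landscapes.

Rapid urbanisation converts farmland, forest and water into construction
land, fragmenting natural habitat and eroding the connectivity that
terrestrial mammals need to move, disperse and exchange genes. Because a
3 km disperser and a 100 km disperser experience the same landscape very
differently, `econetkit` analyses the landscape at **five species-dispersal
scales** — small (10 ha minimum habitat, 3 km maximum dispersal), meso
(60 ha / 10 km), large (300 ha / 30 km), extra-large (500 ha / 60 km) and
ultra-large (1000 ha / 100 km) — and tracks how the resulting ecological
networks and their community structure evolve over a multi-year land-cover
series.

The package is aimed at landscape ecologists and regional planners who
want a tested, scriptable version of the standard
MSPA → resistance → corridor → graph-index workflow, plus
modularity-based ecological groups with life-cycle tracking. It runs
end-to-end on synthetic landscapes, so every stage is testable without any
remote-sensing downloads.

## The method

1. **Habitat identification (MSPA).** Forest, shrub and grassland form the
   binary foreground, which mathematical morphology decomposes into seven
   classes (core, islet, perforation, edge, loop, bridge, branch).
   Connected core areas above the scale's minimum habitat area become
   ecological source patches.
2. **Resistance surface.** Movement cost is a weighted overlay of four
   reclassified factors (class values in [1, 1000]):

   ```
   R_final = 0.32 R_landuse + 0.27 R_dist_construction + 0.22 R_slope + 0.19 R_elevation
   ```

   Under the default tables `R_final` is bounded by [1.00, 853.00].
3. **Corridors (minimum cumulative resistance).** Least-cost paths over the
   8-connected cell graph (step cost = step length × mean endpoint
   resistance) connect patch pairs whose cost distance passes the
   scale's dispersal gate; paths crossing a third source patch are
   discarded. Corridor quality is `CWD_LCPL = cwd / length` (1 on ideal
   habitat; larger is worse) and a least-cost-band width.
4. **Connectivity indices.** Network closure α = (L−V+1)/(2V−5), line-point
   rate β = L/V, connectivity γ = L/(3(V−2)); probability of connectivity
   `PC = Σᵢⱼ aᵢaⱼ p*ᵢⱼ / A_L²` with the max-product movement kernel
   `p = exp(−α·d)` anchored at p = 0.05 for the maximum dispersal distance;
   per-patch `dPC` (leave-one-out loss of PC), area-weighted betweenness
   `BC^PC`, and circuit-theory current flow `CF` (corridors as resistors of
   conductance 1/lcd, all-to-one groundings).
5. **Ecological groups and evolution.** Patches and corridors form a
   weighted graph with `E_ij = aᵢaⱼ e^(−α·d_ij)`; greedy agglomerative
   modularity maximisation yields the groups. Node importance
   `PNI = 0.5·CPI + 0.5·HFI` (normalised BC^PC and area) weights each node;
   a node is a **core node** when `Cen(v) = Σ_nbrs (W_v − W_nbr) > 0`.
   Across consecutive years, groups sharing a core node are related and
   classified into seven life-cycle events: formation, disappearance,
   expansion, shrinkage, stability, split and merger.

## Worked example

```python
import econetkit as ek

config = ek.RunConfig(
    scenario=ek.ScenarioConfig(),   # default synthetic study landscape
    scales=("small",),
    out_dir="demo_run",
    seed=42,
)
result = ek.run_multiscale(config)
```

`demo_run/network_summary.csv` then contains, for the first year:

```
scale  year   V  L     alpha      beta     gamma        pc
small  1990  13  6 -0.285714  0.461538  0.181818  0.055325
```

Thirteen source patches pass the 10 ha screen; six corridors survive the
3 km dispersal gate. α < 0 and β < 1 say the small-scale network is
tree-like with no closed loops — short-range dispersers cannot circulate.
The node table (`nodes_small_1990.csv`) ranks patches by importance; its
top row

```
id  area_ha       dpc  cf    pni  group_id  is_core
 1  1242.72  56.53     4.0  0.50         1    False
```

shows that removing the largest patch would erase 56.5% of the overall
probability of connectivity. Over the four-year series the events table
records 11 stability, 10 formation, 9 disappearance and 1 shrinkage event
at this scale: small, isolated groups churn at the urban fringe while the
large vegetated clusters persist.

A command-line interface mirrors the library
(`econetkit synth | mspa | resistance | network | connectivity | groups |
evolve | run-all`):

```bash
econetkit synth --out demo_landscape --seed 42
econetkit run-all --config demo_landscape/scenario.txt --out demo_run
```

## Outputs

| file | contents |
|---|---|
| `network_summary.csv` | one row per (scale, year): V, L, α, β, γ, PC |
| `nodes_<scale>_<year>.csv` | per patch: area, dPC, BC^PC, CF, PNI, group, core flag |
| `edges_<scale>_<year>.csv` | per corridor: lcd, cwd, length, CWD_LCPL, width |
| `corridors_*.geojson`, `network_*.graphml` | corridor geometry and the patch graph |
| `partitions.csv`, `events.csv` | group membership and life-cycle events |
| `*.asc` | land use, DEM, MSPA classes, resistance (ESRI ASCII grids) |

Raster land-cover codes: 1 construction, 2 water, 3 unused, 4 farmland,
5 grassland, 6 shrub, 7 forest. MSPA codes: 0 background, 1 core, 2 islet,
3 perforation, 4 edge, 5 loop, 6 bridge, 7 branch.
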