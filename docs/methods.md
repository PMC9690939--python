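# Methods

This note documents the models implemented in `econetkit`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic landscapes do and do not emulate.

## Dispersal scales

Analyses run at five fixed species-group scales, each a pair of
(minimum habitat area, maximum dispersal distance): small 10 ha / 3 km,
meso 60 ha / 10 km, large 300 ha / 30 km, extra-large 500 ha / 60 km,
ultra-large 1000 ha / 100 km. The habitat threshold screens MSPA core
components into source patches; the dispersal distance anchors both the
movement-probability kernel and the corridor gate.

## MSPA classification

Foreground = forest ∪ shrub ∪ grassland; everything else (construction,
water, unused, farmland) is background. Morphology uses 8-connected
foreground and 4-connected background (the standard duality that avoids
topological paradoxes) with an edge width of **1 cell (30 m)** by default
— the smallest non-degenerate width; it is a parameter everywhere.

Given width *w*:

* **core** = erosion of the foreground by *w*;
* **islet** = foreground components containing no core;
* the **boundary ring** = (dilation of core by *w*) ∩ foreground \ core is
  labelled **perforation** where a hole (enclosed background) lies within
  *w*, otherwise **edge**; perforation takes precedence over edge at cells
  facing both;
* the remaining foreground consists of **connectors**, subclassed per
  8-connected component by the core components reachable through the
  boundary ring: two or more distinct cores → **bridge**; one core touched
  at two or more disjoint contact zones → **loop**; a single contact →
  **branch**.

Consequences worth knowing: connectors only appear where the foreground is
wider than the ring, so a 1–2 cell corridor's end cells are classified as
edge while its interior is bridge; the fixed precedence
(perforation > edge > bridge > loop > branch) makes the partition
deterministic and exhaustive, which the tests assert on random masks.
Cell area is `cell_size² / 10 000` ha (0.09 ha at 30 m). Patch ids are
assigned by descending area with ties broken by the top-left-most cell.

## Resistance surface

Four factor rasters are reclassified to values in [1, 1000] and combined
with weights 0.32 (land use), 0.27 (distance to construction land),
0.22 (slope), 0.19 (elevation); the weights sum to 1, so the surface is
bounded by [1.00, 853.00] under the default tables (per-factor maxima
1000/900/800/600). Default class tables: land use — construction 1000,
water 900, unused 600, farmland 500, grassland 100, shrub 1, forest 1;
slope (°) — ≤15: 1, 15–30: 200, 30–45: 400, >45: 800; elevation (m) —
≤100: 1, 100–200: 200, 200–400: 400, >400: 600; distance to construction
(m) — ≤200: 900, 200–500: 700, 500–1000: 500, 1000–2000: 300, >2000: 1.

Numerical conventions (the published tables print overlapping interval
endpoints without a rule, so these are package choices, documented and
tested): intervals are **closed on their upper bound** — slope exactly
15° is class 1, elevation exactly 100 m is class 1. Slope comes from
central differences of the DEM over the cell size (`atan(hypot(∂z/∂x,
∂z/∂y))`); distance to construction is the exact Euclidean distance
between cell centres, +∞ (hence the >2000 m class) when the landscape has
no construction at all.

## Corridors and the dispersal gate

Cost distance runs on the 8-connected cell graph with step cost
`step_length · (R(u)+R(v))/2`, the standard raster convention, with
`step_length = cell_size` axially and `cell_size·√2` diagonally. Patch-to-
patch distance is boundary-to-boundary (every patch cell is a Dijkstra
source). The implementation rides on `scipy.sparse.csgraph.dijkstra`; an
independent pure-Python Dijkstra serves as the test oracle, and the two
agree exactly on random grids. The solver's internal ordering is
deterministic, so corridor sets and counts are reproducible; the
least-cost search always runs from the lower-id patch, making
`cwd(a, b) = cwd(b, a)` exact, and the stored distance matrix is
explicitly symmetrised against summation-order round-off.

A pair of patches becomes a corridor iff (i) its least-cost path does not
enter any third source patch (the intermediate-source exclusion), and
(ii) its least-cost distance is at most `max_dispersal_km · 1000 · R_ref`
with `R_ref = 1` — the cost of covering the scale's maximum dispersal
distance over ideal (resistance-1) habitat. The gate is expressed in cost
units because the least-cost distance itself is the inter-patch distance
used throughout; `R_ref` is configurable. Candidate pairs default to all
unordered pairs (`topology="complete"`); a Delaunay-restricted planar
topology is available as an option.

Corridor quality: `CWD_LCPL = cwd / length` equals 1.0 exactly on uniform
unit resistance and grows with the average resistance en route. Corridor
width = (area of the least-cost band — cells whose summed cost distances
to the two endpoints stay within a budget of the optimum) / path length;
the budget defaults to 10% of the corridor's cwd, a package choice since
no band rule is published.

## Connectivity indices

* α = (L−V+1)/(2V−5), β = L/V, γ = L/(3(V−2)); α and γ are reported as
  undefined for V < 3 rather than extrapolated.
* The movement kernel is `p(d) = exp(−α_decay·d)` with
  `α_decay = −ln(p)/d_ref`; the default anchors p = 0.05 at the scale's
  maximum dispersal cost. Max-product path probabilities are computed
  exactly as shortest paths under the log-transformed edge length
  `α_decay · lcd`.
* **PC** uses the standard area-weighted max-product-probability kernel
  normalised by the squared total landscape area (the definition the
  common landscape-graph tools implement; the index is cited but not
  printed in the source tables), with `p*_ii = 1` so isolated patches
  contribute their self terms. `dPC_i = 100·(PC − PC_remove,i)/PC`; values
  lie in [0, 100] but do not sum to 100.
* **BC^PC** credits every *interior* node of the optimal path between each
  unordered pair (j, k) with `a_j·a_k·e^(−α_decay·d_jk)`. Endpoints are
  excluded (the subscript convention `i ∈ P_jk, k < j` read literally);
  an exhaustive simple-path enumeration oracle checks both PC and BC^PC to
  1e−12 relative tolerance on all small graphs.
* **CF**: corridors become resistors with conductance `1/lcd` (the
  simplest monotone mapping; none is published). For each grounded patch
  j, a unit current is injected at every other patch of j's component and
  the node through-current is `½(Σ|I_edge| + |net injection|)`; CF_i sums
  over groundings. CF is invariant under uniform conductance scaling, and
  isolated patches carry 0. The per-network "CF mean" reported by the
  pipeline is the mean over nodes.
* **IIC** is provided as an optional extra using its standard
  topological-distance definition; it takes no part in any calibration.

## Ecological groups and evolution

Edge weights `E_ij = a_i·a_j·e^(−α_decay·lcd_ij)`. Modularity is the
standard weighted Newman form `q = Σ_C [w_in(C)/m − (deg(C)/2m)²]` (the
printed formula in the source is typographically garbled; the standard
form is anchored to the stated principle of dense intra-group, sparse
inter-group links). The greedy optimiser is plain agglomeration: start
from singletons, merge the pair with the largest Δq (ties to the smallest
group-id pair), record every level, return the level of maximum q. On an
edgeless graph the singleton partition is returned with q flagged
undefined. Exhaustive partition enumeration confirms the greedy optimum on
small clustered graphs; on weak-structure dense random graphs plain
greedy agglomeration can land measurably below the optimum (a known
property of the algorithm, shared by other CNM implementations).

Node importance: `PNI = 0.5·CPI + 0.5·HFI` where CPI is min-max-normalised
BC^PC and HFI min-max-normalised patch area; a degenerate component (all
values equal) is set to 0 for all nodes. Core nodes satisfy
`Cen(v) = Σ_{u ∈ A_v} (W_v − W_u) > 0` with `A_v` the node's neighbours in
the **whole network** by default (the published wording does not scope the
neighbourhood; a within-group option exists). The inequality is strict, so
an isolated node (empty sum, Cen = 0) is never core — consequently a
singleton group has no core, relates to no successor, and appears in the
event stream as a disappearance plus a formation even on a frozen
landscape. The frozen-landscape stability check therefore uses a
single-cluster scenario whose network is connected and whose groups all
carry cores.

Cross-year patch identity: a patch maps to the later patch sharing the
most cells, accepted when the overlap covers ≥ 50% of the smaller patch.
Groups C_t and C_{t+1} are related iff a core node of C_t (mapped through
that identity) is a member of C_{t+1}. Relation components classify as:
no successor → disappearance; no predecessor → formation; one-to-one →
stability / expansion / shrinkage by relative member-count change against
τ (default 0.2); one-to-many → split; many-to-one → merger; many-to-many
components are resolved by strongest-overlap pairing, pairs re-classified
one-to-one and leftovers becoming disappearances/formations. Every group
at t and t+1 appears in exactly one event (asserted as a property test).

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes, at
a scaled-down extent chosen so the full five-scale, four-year analysis
runs in seconds: a 300×300 grid of 30 m cells (9 km × 9 km, 8100 ha)
observed in 1990/2000/2010/2020.

* **Terrain**: four octaves of Gaussian-smoothed noise, min-max normalised,
  raised to the power 3.5 and scaled to `relief_amplitude` (default
  600 m). The skew reproduces a coastal-lowland hypsometry — most of the
  landscape below the 100 m resistance class break, with steep isolated
  hills — so that corridors through vegetated lowland carry near-minimum
  resistance, matching corridor-quality ratios of a few units rather than
  hundreds.
* **Water**: one connected 3-cell band following the minimum-elevation
  west–east trace (dynamic programming), a genuine high-resistance
  barrier.
* **Vegetation**: six clusters of forest blocks grown by noisy geodesic
  accretion on valley floors, joined within a cluster by 1-cell shrub
  corridors (which erode away in MSPA, keeping the cores separate patches
  while providing cheap movement routes). The default block-area ladder
  (1300 … 18 ha) spans all five habitat thresholds with margins for
  erosion loss, so the source count strictly decreases across scales.
  Small grassland patches (below every threshold) are seeded preferentially
  between clusters as stepping stones.
* **Urbanisation**: a compact construction agglomeration seeded in the
  farmland matrix far from vegetation, growing by edge accretion — each
  step converts exactly `round(rate · n_cells)` cells (default rate 1% per
  decade for the scaled-down extent), drawn from a band around the urban
  footprint with probability ∝ 1/distance². Construction growth is the
  only change over time, and it is monotone.

Everything is reproducible from the scenario seed.

What the synthetic data does **not** emulate: real land-cover
classification error, seasonal or successional vegetation change,
hydrological DEM structure, anisotropic urban growth along transport
corridors, and the sheer extent of a real study region (tens of thousands
of km², thousands of patches). Passing tests therefore demonstrate the
correctness of each algorithmic stage and the qualitative multi-scale
behaviour (fewer, larger sources and fewer, larger groups as the
dispersal scale grows; corridor quality degrading as construction
spreads), not the published magnitudes, which depend on the real rasters.

## Problem sizes used by tests and the acceptance script

Oracle checks run on exactly enumerable instances: ≤ 25×25 cost grids
against a brute-force Dijkstra (200 draws), ≤ 7-node graphs against
exhaustive simple-path enumeration (50 draws), ≤ 8-node graphs against
exhaustive set-partition search (50 draws). The cross-scale monotonicity
check runs the full default 300×300 scenario. The published-value targets
are closed-form recomputations from the printed corridor counts and
line-point rates, independent of any simulation.
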