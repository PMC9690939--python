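"""Ecological groups: modularity communities of the corridor network,
core-node identification and cross-year evolution tracking.

Patches and corridors form a weighted graph with edge weights

    E_ij = a_i * a_j * exp(-decay_alpha * d_ij)

(the two patch areas damped by the movement-probability kernel over the
least-cost distance). Groups are found by greedy agglomerative
modularity maximisation: starting from singletons, repeatedly merge the
pair of groups with the largest modularity gain (or smallest loss),
recording every level, and return the level of maximum weighted Newman
modularity

    q = sum_C [ w_in(C) / m - (deg(C) / (2 m))^2 ].

Node importance blends patch-location importance (min-max normalised
BC^PC) and habitat-function importance (min-max normalised area):
``PNI = 0.5 CPI + 0.5 HFI``. A node is a core node when its weight
exceeds its neighbours' in aggregate: ``Cen(v) = sum_nbrs (W_v - W_nbr)
> 0`` — strictly positive, no tunable threshold, so an isolated node
(empty sum, Cen = 0) is not core.

Evolution: groups C_t and C_{t+1} are related when a core node of C_t
is a member of C_{t+1} (patches matched across years by majority cell
overlap). Related components classify into the seven life-cycle events:
formation, disappearance, expansion, shrinkage, stability, split and
merger; one-to-one relations compare sizes against a relative tolerance
tau (default 0.2), many-to-many components are resolved by
strongest-overlap pairing and re-classified.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import ConnectivityReport, DistanceDecay
from .corridors import EcoNetwork
from .mspa import SourcePatch

__all__ = [
    "WeightedEcoGraph",
    "GroupPartition",
    "NodeImportance",
    "EvolutionEvent",
    "build_weighted_graph",
    "modularity_score",
    "greedy_modularity",
    "node_importance",
    "core_nodes",
    "match_patches",
    "track_evolution",
    "classify_events",
]

EVENT_TYPES = (
    "formation",
    "disappearance",
    "expansion",
    "shrinkage",
    "stability",
    "split",
    "merger",
)


@dataclass
class WeightedEcoGraph:
    """Patch graph with distance-decay edge weights."""

    graph: nx.Graph  # nodes: patch ids; edge attr "weight" = E_ij

    @property
    def total_edge_weight(self) -> float:
        return float(self.graph.size(weight="weight"))


def build_weighted_graph(network: EcoNetwork, decay: DistanceDecay) -> WeightedEcoGraph:
    """One weighted edge per corridor: ``E_ij = a_i a_j exp(-rate * lcd)``."""
    g = nx.Graph()
    index = {p.id: k for k, p in enumerate(network.patches)}
    for p in network.patches:
        g.add_node(p.id, a=p.attribute)
    rate = decay.rate
    for c in network.corridors:
        d = float(network.lcd[index[c.i], index[c.j]])
        a_i = network.patches[index[c.i]].attribute
        a_j = network.patches[index[c.j]].attribute
        g.add_edge(c.i, c.j, weight=a_i * a_j * math.exp(-rate * d))
    return WeightedEcoGraph(g)


@dataclass
class GroupPartition:
    """A partition of the patch set into ecological groups."""

    year: int
    assignment: dict[int, int]  # node id -> group id
    q: float | None  # None when the graph has no edge weight
    groups: dict[int, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups:
            groups: dict[int, set[int]] = {}
            for node, gid in self.assignment.items():
                groups.setdefault(gid, set()).add(node)
            self.groups = {gid: frozenset(m) for gid, m in groups.items()}

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def modularity_score(graph: WeightedEcoGraph | nx.Graph, assignment: dict[int, int]) -> float | None:
    """Weighted Newman modularity of a partition; None when the graph has
    zero total edge weight (undefined)."""
    g = graph.graph if isinstance(graph, WeightedEcoGraph) else graph
    if set(assignment) != set(g.nodes):
        raise ValueError("partition must cover exactly the graph's nodes")
    m = g.size(weight="weight")
    if m == 0:
        return None
    w_in: dict[int, float] = {}
    deg: dict[int, float] = {}
    for node, gid in assignment.items():
        deg[gid] = deg.get(gid, 0.0) + g.degree(node, weight="weight")
    for u, v, w in g.edges(data="weight", default=1.0):
        if assignment[u] == assignment[v]:
            w_in[assignment[u]] = w_in.get(assignment[u], 0.0) + w
    q = 0.0
    for gid in deg:
        q += w_in.get(gid, 0.0) / m - (deg[gid] / (2.0 * m)) ** 2
    return q


def greedy_modularity(graph: WeightedEcoGraph | nx.Graph, year: int = 0) -> GroupPartition:
    """Agglomerative greedy modularity clustering.

    Starts from singleton groups and at each step merges the pair of
    groups with the maximum modularity change (largest increase or
    smallest decrease; ties broken toward the smallest group-id pair),
    recording all n..1 levels and returning the level of maximum q.
    Groups of the returned partition are renumbered 1..k by their
    smallest member. An edgeless graph keeps all singletons with q
    flagged undefined (None).
    """
    g = graph.graph if isinstance(graph, WeightedEcoGraph) else graph
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("graph has no nodes")
    two_m = 2.0 * g.size(weight="weight")
    assignment = {v: v for v in nodes}
    if two_m == 0:
        return _renumber(GroupPartition(year, assignment, None))

    # e[a][b]: fraction of total edge weight between groups a and b;
    # deg[a]: fraction of weight incident to group a. q = sum(e_aa - deg_a^2)
    e: dict[int, dict[int, float]] = {v: {} for v in nodes}
    deg: dict[int, float] = {v: g.degree(v, weight="weight") / two_m for v in nodes}
    for u, v, w in g.edges(data="weight", default=1.0):
        if u == v:
            continue
        e[u][v] = e[u].get(v, 0.0) + w / two_m
        e[v][u] = e[v].get(u, 0.0) + w / two_m
    q = sum(-d * d for d in deg.values())

    best_q, best_assignment = q, dict(assignment)
    active = set(nodes)
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(e[a]):
                if b <= a:
                    continue
                dq = 2.0 * (e[a].get(b, 0.0) - deg[a] * deg[b])
                if best is None or dq > best[0] + 1e-15:
                    best = (dq, a, b)
        if best is None:
            # only disconnected groups remain; further merges cannot help
            break
        dq, a, b = best
        # merge b into a
        for c, w in e[b].items():
            if c == a:
                continue
            e[a][c] = e[a].get(c, 0.0) + w
            e[c][a] = e[c].get(a, 0.0) + w
            del e[c][b]
        e[a].pop(b, None)
        del e[b]
        deg[a] += deg.pop(b)
        for node, gid in assignment.items():
            if gid == b:
                assignment[node] = a
        active.discard(b)
        q += dq
        if q > best_q + 1e-12:
            best_q, best_assignment = q, dict(assignment)

    return _renumber(GroupPartition(year, best_assignment, best_q))


def _renumber(partition: GroupPartition) -> GroupPartition:
    order = sorted(partition.groups.values(), key=min)
    relabel = {}
    for new_id, members in enumerate(order, start=1):
        for v in members:
            relabel[v] = new_id
    return GroupPartition(partition.year, relabel, partition.q)


@dataclass
class NodeImportance:
    """Blended patch importance and core-node flag."""

    cpi: float
    hfi: float
    pni: float
    cen: float = 0.0
    is_core: bool = False


def _minmax(values: dict[int, float]) -> dict[int, float]:
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        # degenerate normalisation: no spread carries no information
        return {k: 0.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def node_importance(
    report: ConnectivityReport, patches: list[SourcePatch]
) -> dict[int, NodeImportance]:
    """PNI = 0.5 * CPI + 0.5 * HFI per patch (min-max normalised BC^PC
    and area)."""
    if not patches:
        return {}
    cpi = _minmax({p.id: report.bcpc.get(p.id, 0.0) for p in patches})
    hfi = _minmax({p.id: p.area_ha for p in patches})
    return {
        p.id: NodeImportance(
            cpi=cpi[p.id], hfi=hfi[p.id], pni=0.5 * cpi[p.id] + 0.5 * hfi[p.id]
        )
        for p in patches
    }


def core_nodes(
    graph: WeightedEcoGraph | nx.Graph,
    weights: dict[int, float],
    scope: str = "graph",
    partition: GroupPartition | None = None,
) -> dict[int, float]:
    """Centrality ``Cen(v) = sum over neighbours (W_v - W_nbr)``.

    A node is core iff Cen(v) > 0 (strict); the empty sum of an isolated
    node is 0, hence non-core. ``scope="graph"`` (default) takes
    neighbours in the whole network; ``scope="group"`` restricts them to
    the node's own group (requires ``partition``). Returns
    ``{node: Cen(v)}``.
    """
    g = graph.graph if isinstance(graph, WeightedEcoGraph) else graph
    if scope not in ("graph", "group"):
        raise ValueError("scope must be 'graph' or 'group'")
    if scope == "group" and partition is None:
        raise ValueError("group scope requires a partition")
    cen = {}
    for v in g.nodes:
        nbrs = g[v]
        if scope == "group":
            gid = partition.assignment[v]  # type: ignore[union-attr]
            nbrs = [u for u in nbrs if partition.assignment[u] == gid]  # type: ignore[union-attr]
        cen[v] = sum(weights[v] - weights[u] for u in nbrs)
    return cen


def is_core(cen: dict[int, float]) -> dict[int, bool]:
    return {v: c > 0 for v, c in cen.items()}


def match_patches(
    patches_t: list[SourcePatch], patches_t1: list[SourcePatch], min_overlap: float = 0.5
) -> dict[int, int]:
    """Cross-year patch identity by cell overlap.

    Patch i at time t maps to the t+1 patch sharing the largest number
    of cells, provided the overlap covers at least ``min_overlap`` of the
    smaller patch; greatest overlap wins.
    """
    mapping: dict[int, int] = {}
    for p in patches_t:
        best_id, best_shared = None, 0
        for p1 in patches_t1:
            shared = len(p.cells & p1.cells)
            if shared > best_shared:
                best_id, best_shared = p1.id, shared
        if best_id is not None:
            other = next(q for q in patches_t1 if q.id == best_id)
            smaller = min(len(p.cells), len(other.cells))
            if best_shared >= min_overlap * smaller:
                mapping[p.id] = best_id
    return mapping


def track_evolution(
    partition_t: GroupPartition,
    cores_t: dict[int, bool],
    partition_t1: GroupPartition,
    identity: dict[int, int] | None = None,
) -> set[tuple[int, int]]:
    """Bipartite evolution relation between two partitions.

    ``(C, C')`` is related iff some core node of C (mapped through the
    cross-year ``identity``; the identity map by default) is a member of
    C'. Groups with no core node relate to nothing.
    """
    if identity is None:
        identity = {v: v for v in partition_t.assignment}
    member_of_t1 = partition_t1.assignment
    relation = set()
    for gid, members in partition_t.groups.items():
        for v in members:
            if not cores_t.get(v, False):
                continue
            v1 = identity.get(v)
            if v1 is not None and v1 in member_of_t1:
                relation.add((gid, member_of_t1[v1]))
    return relation


@dataclass
class EvolutionEvent:
    """One life-cycle event between consecutive time steps."""

    type: str
    groups_t: frozenset[int]
    groups_t1: frozenset[int]

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


def _size_event(n_t: int, n_t1: int, tau: float) -> str:
    change = (n_t1 - n_t) / n_t
    if change > tau:
        return "expansion"
    if change < -tau:
        return "shrinkage"
    return "stability"


def classify_events(
    relation: set[tuple[int, int]],
    partition_t: GroupPartition,
    partition_t1: GroupPartition,
    identity: dict[int, int] | None = None,
    tau: float = 0.2,
) -> list[EvolutionEvent]:
    """Classify the bipartite relation into the seven life-cycle events.

    Every group at t and at t+1 appears in exactly one event. Connected
    relation components map to: no successor -> disappearance, no
    predecessor -> formation, one-to-one -> stability / expansion /
    shrinkage by relative size change against tau, one-to-many -> split,
    many-to-one -> merger. Many-to-many components are resolved by
    strongest-overlap pairing (shared mapped members); the pairs classify
    one-to-one and leftovers classify as disappearance / formation.
    """
    if identity is None:
        identity = {v: v for v in partition_t.assignment}

    bip = nx.Graph()
    t_names = {gid: ("t", gid) for gid in partition_t.groups}
    t1_names = {gid: ("t1", gid) for gid in partition_t1.groups}
    bip.add_nodes_from(t_names.values())
    bip.add_nodes_from(t1_names.values())
    for a, b in relation:
        bip.add_edge(t_names[a], t1_names[b])

    def overlap(gid_t: int, gid_t1: int) -> int:
        mapped = {identity.get(v) for v in partition_t.groups[gid_t]}
        return len(mapped & set(partition_t1.groups[gid_t1]))

    events: list[EvolutionEvent] = []
    for comp in nx.connected_components(bip):
        side_t = sorted(g for s, g in comp if s == "t")
        side_t1 = sorted(g for s, g in comp if s == "t1")
        if not side_t1:
            for gid in side_t:
                events.append(EvolutionEvent("disappearance", frozenset([gid]), frozenset()))
        elif not side_t:
            for gid in side_t1:
                events.append(EvolutionEvent("formation", frozenset(), frozenset([gid])))
        elif len(side_t) == 1 and len(side_t1) == 1:
            kind = _size_event(
                len(partition_t.groups[side_t[0]]),
                len(partition_t1.groups[side_t1[0]]),
                tau,
            )
            events.append(EvolutionEvent(kind, frozenset(side_t), frozenset(side_t1)))
        elif len(side_t) == 1:
            events.append(EvolutionEvent("split", frozenset(side_t), frozenset(side_t1)))
        elif len(side_t1) == 1:
            events.append(EvolutionEvent("merger", frozenset(side_t), frozenset(side_t1)))
        else:
            # many-to-many: strongest-overlap pairing, then re-classify
            pairs = sorted(
                itertools.product(side_t, side_t1),
                key=lambda p: (-overlap(p[0], p[1]), p),
            )
            used_t: set[int] = set()
            used_t1: set[int] = set()
            for a, b in pairs:
                if a in used_t or b in used_t1:
                    continue
                used_t.add(a)
                used_t1.add(b)
                kind = _size_event(
                    len(partition_t.groups[a]), len(partition_t1.groups[b]), tau
                )
                events.append(EvolutionEvent(kind, frozenset([a]), frozenset([b])))
            for gid in side_t:
                if gid not in used_t:
                    events.append(
                        EvolutionEvent("disappearance", frozenset([gid]), frozenset())
                    )
            for gid in side_t1:
                if gid not in used_t1:
                    events.append(
                        EvolutionEvent("formation", frozenset(), frozenset([gid]))
                    )
    return events
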