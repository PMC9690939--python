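"""Graph-, patch- and circuit-level connectivity indices of an ecological
network.

Network level (edge count L, node count V):

    alpha = (L - V + 1) / (2V - 5)     network closure (loops)
    beta  = L / V                      line-point rate (edges per node)
    gamma = L / (3 (V - 2))            network connectivity

alpha and gamma require V >= 3 and are flagged undefined otherwise.

Patch level: the probability of connectivity

    PC = sum_i sum_j a_i a_j p*_ij / A_L^2

with patch attributes a (areas, ha), landscape area A_L, and p*_ij the
maximum product of step probabilities ``exp(-decay_alpha * lcd)`` along
network paths (p*_ii = 1). ``dPC_i = 100 (PC - PC_remove,i) / PC`` scores
each patch by the connectivity lost on its removal. The area-weighted
betweenness BC^PC credits every interior node of the maximum-probability
path between each pair (j, k) with ``a_j a_k exp(-decay_alpha d_jk)``.

Circuit level: corridors become resistors of conductance ``1 / lcd``; for
each grounded patch j a unit current is injected at every other patch and
Kirchhoff's equations are solved on the component; CF_i accumulates the
current through patch i over all groundings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .corridors import EcoNetwork

__all__ = [
    "DistanceDecay",
    "ConnectivityReport",
    "alpha_beta_gamma",
    "decay_alpha",
    "DistanceDecay",
    "probability_of_connectivity",
    "delta_pc",
    "bc_pc",
    "current_flow",
    "iic",
    "connectivity_report",
]


def decay_alpha(p: float, d: float) -> float:
    """Distance-decay constant: ``-ln(p) / d``.

    ``exp(-decay_alpha(p, d) * d) == p`` by construction. Named after the
    decay parameter of the movement-probability kernel; distinct from the
    network-closure alpha index.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability p must lie in (0, 1), got {p}")
    if not d > 0:
        raise ValueError(f"reference distance must be positive, got {d}")
    return -math.log(p) / d


@dataclass(frozen=True)
class DistanceDecay:
    """Movement-probability kernel ``p(d) = exp(-decay_alpha * d)``,
    anchored so probability ``p`` is reached at distance ``d_ref``
    (cost units). The maximum dispersal distance conventionally anchors
    p = 0.05."""

    p: float
    d_ref: float

    def __post_init__(self) -> None:
        decay_alpha(self.p, self.d_ref)  # validate

    @property
    def rate(self) -> float:
        return decay_alpha(self.p, self.d_ref)

    def probability(self, d: float) -> float:
        return math.exp(-self.rate * d)

    @classmethod
    def for_scale_km(cls, max_dispersal_km: float, p: float = 0.05) -> "DistanceDecay":
        """Kernel anchored at the scale's maximum dispersal cost
        (km * 1000 cost units, ideal-habitat convention)."""
        return cls(p=p, d_ref=max_dispersal_km * 1000.0)


def alpha_beta_gamma(
    network_or_L: EcoNetwork | int, V: int | None = None
) -> tuple[float | None, float, float | None]:
    """Closure, line-point rate and connectivity indices from L and V.

    Accepts an :class:`EcoNetwork` or explicit ``(L, V)`` counts. alpha
    and gamma are None (undefined) for V < 3.
    """
    if isinstance(network_or_L, EcoNetwork):
        L, V = network_or_L.n_edges, network_or_L.n_nodes
    else:
        L = int(network_or_L)
        if V is None:
            raise ValueError("V is required when passing L directly")
    if V <= 0:
        raise ValueError("network has no nodes")
    beta = L / V
    if V < 3:
        return None, beta, None
    alpha = (L - V + 1) / (2 * V - 5)
    gamma = L / (3 * (V - 2))
    return alpha, beta, gamma


def _probability_graph(network: EcoNetwork, decay: DistanceDecay) -> nx.Graph:
    """Network graph with additive edge lengths ``decay_alpha * lcd`` so the
    maximum-product-probability path is the shortest path (log transform)."""
    g = nx.Graph()
    index = {p.id: k for k, p in enumerate(network.patches)}
    for p in network.patches:
        g.add_node(p.id, a=p.attribute)
    rate = decay.rate
    for c in network.corridors:
        d = float(network.lcd[index[c.i], index[c.j]])
        g.add_edge(c.i, c.j, cost=rate * d, lcd=d)
    return g


def _pc_value(g: nx.Graph, area_total: float) -> float:
    """PC from a probability graph (nodes carry attribute ``a``)."""
    if g.number_of_nodes() == 0:
        return 0.0
    total = 0.0
    attrs = dict(g.nodes(data="a"))
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="cost"):
        a_src = attrs[src]
        for dst, cost in lengths.items():
            total += a_src * attrs[dst] * math.exp(-cost)
    # unreached ordered pairs contribute nothing (p* = 0); self terms
    # (cost 0 -> p* = 1) are included by the traversal
    return total / area_total**2


def probability_of_connectivity(network: EcoNetwork, decay: DistanceDecay) -> float:
    """Overall probability of connectivity of the network."""
    return _pc_value(_probability_graph(network, decay), network.landscape_area_ha)


def delta_pc(network: EcoNetwork, decay: DistanceDecay) -> dict[int, float]:
    """Per-patch dPC: percentage of PC lost when the patch (and its
    corridors) is removed. Flagged undefined (empty dict) when PC = 0."""
    g = _probability_graph(network, decay)
    pc = _pc_value(g, network.landscape_area_ha)
    if pc == 0:
        return {}
    out = {}
    for p in network.patches:
        h = g.copy()
        h.remove_node(p.id)
        pc_removed = _pc_value(h, network.landscape_area_ha)
        out[p.id] = 100.0 * (pc - pc_removed) / pc
    return out


def bc_pc(network: EcoNetwork, decay: DistanceDecay) -> dict[int, float]:
    """Area- and probability-weighted betweenness centrality.

    For every unordered patch pair (j, k) the maximum-product-probability
    path contributes ``a_j a_k exp(-decay_alpha d_jk)`` to each of its
    interior nodes (endpoints excluded); d_jk is the path's total cost
    distance. Disconnected pairs contribute nothing.
    """
    g = _probability_graph(network, decay)
    scores = {p.id: 0.0 for p in network.patches}
    attrs = dict(g.nodes(data="a"))
    rate = decay.rate
    nodes = sorted(g.nodes)
    for idx, j in enumerate(nodes):
        costs, paths = nx.single_source_dijkstra(g, j, weight="cost")
        for k in nodes[idx + 1 :]:
            if k not in costs:
                continue
            d_jk = costs[k] / rate if rate > 0 else 0.0
            weight = attrs[j] * attrs[k] * math.exp(-rate * d_jk)
            for interior in paths[k][1:-1]:
                scores[interior] += weight
    return scores


def current_flow(network: EcoNetwork) -> dict[int, float]:
    """Circuit-theory current flow through each patch.

    Corridors are resistors with conductance 1/lcd. For each ground
    patch j, every other patch of j's component injects a unit current;
    the through-current at patch i is half the sum of absolute edge
    currents at i plus its absolute net injection. CF_i sums these over
    all groundings. Isolated patches carry no current (CF = 0).
    """
    g = _probability_graph(network, DistanceDecay(p=0.5, d_ref=1.0))
    cf = {p.id: 0.0 for p in network.patches}
    for component in nx.connected_components(g):
        nodes = sorted(component)
        n = len(nodes)
        if n < 2:
            continue
        pos = {v: k for k, v in enumerate(nodes)}
        lap = np.zeros((n, n))
        for u, v, data in g.subgraph(component).edges(data=True):
            c = 1.0 / data["lcd"]
            lap[pos[u], pos[u]] += c
            lap[pos[v], pos[v]] += c
            lap[pos[u], pos[v]] -= c
            lap[pos[v], pos[u]] -= c
        for ground in nodes:
            gi = pos[ground]
            keep = [k for k in range(n) if k != gi]
            b = np.ones(n)
            b[gi] = 0.0
            volts = np.zeros(n)
            volts[keep] = np.linalg.solve(lap[np.ix_(keep, keep)], b[keep])
            # through-current: half of (sum |edge currents| + |net injection|)
            injection = np.ones(n)
            injection[gi] = -(n - 1)
            for v in nodes:
                k = pos[v]
                edge_abs = 0.0
                for u in g[v]:
                    if u in pos:
                        edge_abs += abs(
                            (volts[k] - volts[pos[u]]) / g[v][u]["lcd"]
                        )
                cf[v] += 0.5 * (edge_abs + abs(injection[k]))
    return cf


def iic(network: EcoNetwork) -> float:
    """Integral index of connectivity (standard definition, optional
    extra): ``sum a_i a_j / (1 + nl_ij) / A_L^2`` with nl the topological
    link count of the shortest network path."""
    g = _probability_graph(network, DistanceDecay(p=0.5, d_ref=1.0))
    attrs = dict(g.nodes(data="a"))
    total = 0.0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, nl in lengths.items():
            total += attrs[src] * attrs[dst] / (1.0 + nl)
    return total / network.landscape_area_ha**2


@dataclass
class ConnectivityReport:
    """Network-, node- and edge-level connectivity summary."""

    scale: str
    year: int
    n_nodes: int
    n_edges: int
    alpha_index: float | None
    beta_index: float
    gamma_index: float | None
    pc: float
    dpc: dict[int, float]
    bcpc: dict[int, float]
    cf: dict[int, float]

    def network_row(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scale": self.scale,
                    "year": self.year,
                    "V": self.n_nodes,
                    "L": self.n_edges,
                    "alpha": self.alpha_index,
                    "beta": self.beta_index,
                    "gamma": self.gamma_index,
                    "pc": self.pc,
                }
            ]
        )

    def node_table(self, network: EcoNetwork) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": p.id,
                    "area_ha": p.area_ha,
                    "dpc": self.dpc.get(p.id, float("nan")),
                    "bcpc": self.bcpc.get(p.id, 0.0),
                    "cf": self.cf.get(p.id, 0.0),
                }
                for p in network.patches
            ],
            columns=["id", "area_ha", "dpc", "bcpc", "cf"],
        )


def connectivity_report(network: EcoNetwork, decay: DistanceDecay) -> ConnectivityReport:
    """Compute every connectivity index for one network."""
    alpha, beta, gamma = (
        alpha_beta_gamma(network) if network.n_nodes else (None, float("nan"), None)
    )
    return ConnectivityReport(
        scale=network.scale.name,
        year=network.year,
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        alpha_index=alpha,
        beta_index=beta,
        gamma_index=gamma,
        pc=probability_of_connectivity(network, decay),
        dpc=delta_pc(network, decay),
        bcpc=bc_pc(network, decay),
        cf=current_flow(network),
    )
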