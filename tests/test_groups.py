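"""Ecological groups: weighted-graph construction, modularity and greedy
clustering against exhaustive search, node importance, core nodes and the
seven life-cycle events."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from econetkit import (
    DistanceDecay,
    GroupPartition,
    build_weighted_graph,
    classify_events,
    core_nodes,
    greedy_modularity,
    is_core,
    match_patches,
    modularity_score,
    node_importance,
    track_evolution,
)
from econetkit.connectivity import ConnectivityReport
from econetkit.mspa import SourcePatch
from helpers import all_partitions, make_network

UNIT_DECAY = DistanceDecay(p=math.exp(-1.0), d_ref=1.0)


def two_triangles():
    g = nx.Graph()
    g.add_edges_from(
        [(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)], weight=1.0
    )
    return g


def partition_of(groups):
    assignment = {v: gid for gid, members in enumerate(groups) for v in members}
    return assignment


class TestWeightedGraph:
    def test_zero_distance_unit_areas(self):
        net = make_network({1: 1.0, 2: 1.0}, [(1, 2, 0.0)])
        g = build_weighted_graph(net, UNIT_DECAY).graph
        assert g[1][2]["weight"] == pytest.approx(1.0)

    def test_bilinear_in_areas(self):
        d = 0.7
        w1 = build_weighted_graph(
            make_network({1: 2.0, 2: 3.0}, [(1, 2, d)]), UNIT_DECAY
        ).graph[1][2]["weight"]
        w2 = build_weighted_graph(
            make_network({1: 4.0, 2: 6.0}, [(1, 2, d)]), UNIT_DECAY
        ).graph[1][2]["weight"]
        assert w2 == pytest.approx(4 * w1)

    def test_matches_direct_formula(self, rng):
        areas = {i: float(rng.uniform(1, 9)) for i in range(1, 6)}
        edges = [(1, 2, 0.3), (2, 3, 1.4), (3, 4, 0.2), (4, 5, 2.2)]
        g = build_weighted_graph(make_network(areas, edges), UNIT_DECAY).graph
        rate = UNIT_DECAY.rate
        for i, j, d in edges:
            assert g[i][j]["weight"] == pytest.approx(
                areas[i] * areas[j] * math.exp(-rate * d), rel=1e-12
            )


class TestModularity:
    def test_single_cluster_is_zero(self):
        g = two_triangles()
        q = modularity_score(g, {v: 0 for v in g})
        assert q == pytest.approx(0.0, abs=1e-15)

    def test_two_disjoint_triangles_half(self):
        q = modularity_score(two_triangles(), partition_of([{1, 2, 3}, {4, 5, 6}]))
        assert q == pytest.approx(0.5)

    def test_half_is_the_exhaustive_optimum(self):
        g = two_triangles()
        best = max(
            modularity_score(g, partition_of(p)) for p in all_partitions(sorted(g))
        )
        assert best == pytest.approx(0.5)

    def test_singletons_on_complete_graph_negative(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert modularity_score(g, {v: v for v in g}) < 0

    def test_matches_networkx_on_random_partitions(self, rng):
        g = nx.gnp_random_graph(9, 0.4, seed=7)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 3.0))
        labels = {v: int(rng.integers(3)) for v in g}
        communities = [
            {v for v, l in labels.items() if l == c} for c in set(labels.values())
        ]
        expected = nx.algorithms.community.modularity(g, communities, weight="weight")
        assert modularity_score(g, labels) == pytest.approx(expected, rel=1e-12)

    def test_zero_weight_graph_flagged(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        assert modularity_score(g, {1: 0, 2: 1}) is None


class TestGreedy:
    def test_recovers_disjoint_triangles(self):
        part = greedy_modularity(two_triangles())
        assert part.q == pytest.approx(0.5)
        assert set(part.groups.values()) == {frozenset({1, 2, 3}), frozenset({4, 5, 6})}

    def test_edgeless_graph_keeps_singletons(self):
        g = nx.Graph()
        g.add_nodes_from([3, 1, 2])
        part = greedy_modularity(g)
        assert part.q is None
        assert part.n_groups == 3

    def test_deterministic(self, rng):
        g = nx.gnp_random_graph(10, 0.35, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
        a = greedy_modularity(g)
        b = greedy_modularity(g)
        assert a.assignment == b.assignment and a.q == b.q

    def test_partition_is_valid_cover(self, rng):
        g = nx.gnp_random_graph(12, 0.3, seed=11)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = greedy_modularity(g)
        members = [v for grp in part.groups.values() for v in grp]
        assert sorted(members) == sorted(g.nodes)

    @pytest.mark.parametrize("seed", range(6))
    def test_near_optimal_on_clustered_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        k = n // 2
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in itertools.combinations(range(n), 2):
            same = (i < k) == (j < k)
            if rng.random() < (0.8 if same else 0.15):
                w = rng.uniform(0.5, 2.0) if same else rng.uniform(0.05, 0.3)
                g.add_edge(i, j, weight=float(w))
        if g.number_of_edges() == 0:
            return
        part = greedy_modularity(g)
        best = max(
            modularity_score(g, partition_of(p)) for p in all_partitions(sorted(g))
        )
        if best > 1e-12:
            assert part.q >= 0.95 * best


class TestNodeImportance:
    def report_for(self, bcpc, patches):
        return ConnectivityReport(
            scale="small", year=0, n_nodes=len(patches), n_edges=0,
            alpha_index=None, beta_index=0.0, gamma_index=None,
            pc=0.0, dpc={}, bcpc=bcpc, cf={},
        )

    def patches_with_areas(self, areas):
        return [
            SourcePatch(id=i, cells=frozenset({(i, 0)}), area_ha=a)
            for i, a in areas.items()
        ]

    def test_extremes(self):
        patches = self.patches_with_areas({1: 10.0, 2: 50.0, 3: 30.0})
        imp = node_importance(self.report_for({1: 0.0, 2: 8.0, 3: 2.0}, patches), patches)
        assert imp[2].pni == pytest.approx(1.0)
        assert imp[1].pni == pytest.approx(0.0)

    def test_hand_normalised_fixture(self):
        patches = self.patches_with_areas({1: 10.0, 2: 20.0, 3: 30.0, 4: 40.0})
        imp = node_importance(self.report_for({1: 0.0, 2: 1.0, 3: 3.0, 4: 4.0}, patches), patches)
        assert imp[2].cpi == pytest.approx(0.25)
        assert imp[2].hfi == pytest.approx(1 / 3)
        assert imp[2].pni == pytest.approx(0.5 * 0.25 + 0.5 / 3)

    def test_affine_invariance_of_cpi(self):
        patches = self.patches_with_areas({1: 5.0, 2: 6.0, 3: 7.0})
        raw = {1: 0.2, 2: 0.9, 3: 0.5}
        scaled = {k: 100.0 * v + 7.0 for k, v in raw.items()}
        a = node_importance(self.report_for(raw, patches), patches)
        b = node_importance(self.report_for(scaled, patches), patches)
        for i in raw:
            assert a[i].pni == pytest.approx(b[i].pni, rel=1e-12)

    def test_degenerate_component_zeroed(self):
        patches = self.patches_with_areas({1: 10.0, 2: 10.0})
        imp = node_importance(self.report_for({1: 3.0, 2: 5.0}, patches), patches)
        assert imp[1].hfi == imp[2].hfi == 0.0


class TestCoreNodes:
    def test_hand_example_on_path(self):
        g = nx.path_graph([1, 2, 3])
        cen = core_nodes(g, {1: 0.5, 2: 0.9, 3: 0.3})
        assert cen[2] == pytest.approx(1.0)
        assert cen[1] == pytest.approx(-0.4)
        cores = is_core(cen)
        assert cores == {1: False, 2: True, 3: False}

    def test_isolated_node_not_core(self):
        g = nx.Graph()
        g.add_node(7)
        assert is_core(core_nodes(g, {7: 0.99})) == {7: False}

    def test_equal_weights_give_no_cores(self):
        g = nx.cycle_graph([1, 2, 3, 4])
        cores = is_core(core_nodes(g, {v: 0.4 for v in g}))
        assert not any(cores.values())

    def test_group_scope_restricts_neighbours(self):
        g = nx.path_graph([1, 2, 3])
        part = GroupPartition(year=0, assignment={1: 1, 2: 1, 3: 2}, q=None)
        w = {1: 0.5, 2: 0.6, 3: 0.9}
        whole = core_nodes(g, w)
        scoped = core_nodes(g, w, scope="group", partition=part)
        assert whole[2] == pytest.approx((0.6 - 0.5) + (0.6 - 0.9))
        assert scoped[2] == pytest.approx(0.6 - 0.5)


class TestEvolution:
    def patches_at(self, cells_by_id):
        return [
            SourcePatch(id=i, cells=frozenset(cells), area_ha=len(cells) * 0.09)
            for i, cells in cells_by_id.items()
        ]

    def test_patch_matching_by_overlap(self):
        t0 = self.patches_at({1: {(0, 0), (0, 1), (0, 2), (1, 0)}})
        t1 = self.patches_at({5: {(0, 0), (0, 1), (0, 2)}, 6: {(9, 9)}})
        assert match_patches(t0, t1) == {1: 5}

    def test_insufficient_overlap_unmatched(self):
        t0 = self.patches_at({1: {(0, 0), (0, 1), (1, 0)}})
        t1 = self.patches_at({2: {(0, 1), (5, 5), (5, 6), (5, 7)}})
        # shares 1 of 3 cells of the smaller patch: below the 50% rule
        assert match_patches(t0, t1) == {}

    def test_identity_relation_for_identical_partitions(self):
        part = GroupPartition(year=0, assignment={1: 1, 2: 1, 3: 2}, q=None)
        part1 = GroupPartition(year=1, assignment={1: 1, 2: 1, 3: 2}, q=None)
        cores = {1: True, 2: False, 3: True}
        assert track_evolution(part, cores, part1) == {(1, 1), (2, 2)}

    def test_cores_landing_in_two_groups_relate_to_both(self):
        part = GroupPartition(year=0, assignment={1: 1, 2: 1}, q=None)
        part1 = GroupPartition(year=1, assignment={1: 1, 2: 2}, q=None)
        relation = track_evolution(part, {1: True, 2: True}, part1)
        assert relation == {(1, 1), (1, 2)}

    def test_group_without_core_relates_to_nothing(self):
        part = GroupPartition(year=0, assignment={1: 1, 2: 1}, q=None)
        part1 = GroupPartition(year=1, assignment={1: 1, 2: 1}, q=None)
        assert track_evolution(part, {1: False, 2: False}, part1) == set()


class TestEventClassification:
    def classify(self, groups_t, cores_t, groups_t1, tau=0.2):
        part_t = GroupPartition(year=0, assignment=partition_of(groups_t), q=None)
        part_t1 = GroupPartition(year=1, assignment=partition_of(groups_t1), q=None)
        relation = track_evolution(part_t, cores_t, part_t1)
        return classify_events(relation, part_t, part_t1, tau=tau)

    def test_stability(self):
        events = self.classify([{1, 2}], {1: True, 2: False}, [{1, 2}])
        assert [e.type for e in events] == ["stability"]

    def test_expansion(self):
        events = self.classify([{1, 2}], {1: True}, [{1, 2, 3, 4}])
        assert [e.type for e in events] == ["expansion"]

    def test_shrinkage(self):
        events = self.classify([{1, 2, 3, 4}], {1: True}, [{1}], tau=0.2)
        assert [e.type for e in events] == ["shrinkage"]

    def test_formation(self):
        events = self.classify([{1, 2}], {1: True}, [{1, 2}, {8, 9}])
        assert sorted(e.type for e in events) == ["formation", "stability"]

    def test_disappearance(self):
        events = self.classify([{1, 2}, {8, 9}], {1: True, 8: False, 9: False}, [{1, 2}])
        assert sorted(e.type for e in events) == ["disappearance", "stability"]

    def test_split(self):
        events = self.classify(
            [{1, 2, 3, 4, 5, 6}], {1: True, 4: True}, [{1, 2, 3}, {4, 5, 6}]
        )
        assert [e.type for e in events] == ["split"]
        assert events[0].groups_t1 == frozenset({0, 1})

    def test_merger(self):
        events = self.classify(
            [{1, 2}, {3, 4}], {1: True, 3: True}, [{1, 2, 3, 4}]
        )
        assert [e.type for e in events] == ["merger"]

    def test_every_group_in_exactly_one_event(self, rng):
        nodes = list(range(1, 13))
        for _ in range(20):
            assign_t = {v: int(rng.integers(4)) for v in nodes}
            assign_t1 = {v: int(rng.integers(4)) for v in nodes}
            cores = {v: bool(rng.random() < 0.5) for v in nodes}
            part_t = GroupPartition(year=0, assignment=assign_t, q=None)
            part_t1 = GroupPartition(year=1, assignment=assign_t1, q=None)
            relation = track_evolution(part_t, cores, part_t1)
            events = classify_events(relation, part_t, part_t1)
            seen_t = [g for e in events for g in e.groups_t]
            seen_t1 = [g for e in events for g in e.groups_t1]
            assert sorted(seen_t) == sorted(part_t.groups)
            assert sorted(seen_t1) == sorted(part_t1.groups)
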