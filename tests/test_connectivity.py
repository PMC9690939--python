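"""Connectivity indices: network closure formulas, the distance-decay
kernel, PC/dPC/BC^PC against exhaustive path enumeration, and circuit
current flow against hand-solved Kirchhoff systems."""

import itertools
import math

import numpy as np
import pytest

from econetkit import (
    DistanceDecay,
    alpha_beta_gamma,
    bc_pc,
    current_flow,
    decay_alpha,
    delta_pc,
    iic,
    probability_of_connectivity,
)
from helpers import bcpc_oracle, make_network, pc_oracle

UNIT_DECAY = DistanceDecay(p=math.exp(-1.0), d_ref=1.0)  # rate exactly 1


def random_abstract_network(rng, n_max=7, area_total=100.0):
    n = int(rng.integers(2, n_max + 1))
    areas = {i: float(rng.uniform(0.5, 10.0)) for i in range(1, n + 1)}
    edges = []
    for i, j in itertools.combinations(range(1, n + 1), 2):
        if rng.random() < 0.45:
            edges.append((i, j, float(rng.uniform(0.2, 3.0))))
    return areas, edges, make_network(areas, edges, landscape_area_ha=area_total)


class TestAlphaBetaGamma:
    def test_tree_has_zero_closure(self):
        for v in (3, 5, 12):
            alpha, beta, gamma = alpha_beta_gamma(v - 1, v)
            assert alpha == 0.0
            assert beta == pytest.approx((v - 1) / v)

    def test_complete_four_node_graph(self):
        alpha, beta, gamma = alpha_beta_gamma(6, 4)
        assert (alpha, beta, gamma) == (1.0, 1.5, 1.0)

    def test_undefined_below_three_nodes(self):
        alpha, beta, gamma = alpha_beta_gamma(1, 2)
        assert alpha is None and gamma is None
        assert beta == 0.5

    def test_on_network_object(self):
        net = make_network({1: 1, 2: 1, 3: 1}, [(1, 2, 1.0), (2, 3, 1.0)])
        alpha, beta, gamma = alpha_beta_gamma(net)
        assert alpha == 0.0 and beta == pytest.approx(2 / 3) and gamma == pytest.approx(2 / 3)


class TestDecay:
    def test_half_probability_at_unit_distance(self):
        assert decay_alpha(0.5, 1.0) == pytest.approx(math.log(2))

    def test_maximum_dispersal_anchor(self):
        # p = 0.05 at a 30 km cost distance
        assert decay_alpha(0.05, 30_000.0) == pytest.approx(9.986e-5, rel=1e-3)

    @pytest.mark.parametrize("p,d", [(0.05, 3000.0), (0.3, 7.0), (0.9, 120.0)])
    def test_round_trip_identity(self, p, d):
        assert math.exp(-decay_alpha(p, d) * d) == pytest.approx(p, rel=1e-14)

    @pytest.mark.parametrize("p,d", [(0.0, 1.0), (1.0, 1.0), (1.5, 1.0), (0.5, 0.0)])
    def test_domain_errors(self, p, d):
        with pytest.raises(ValueError):
            decay_alpha(p, d)

    def test_scale_kernel(self):
        kernel = DistanceDecay.for_scale_km(3.0, p=0.05)
        assert kernel.probability(3000.0) == pytest.approx(0.05)


class TestProbabilityOfConnectivity:
    def test_single_patch_self_term(self):
        net = make_network({1: 5.0}, [], landscape_area_ha=50.0)
        assert probability_of_connectivity(net, UNIT_DECAY) == pytest.approx(25.0 / 2500.0)

    def test_two_isolated_patches(self):
        net = make_network({1: 3.0, 2: 4.0}, [], landscape_area_ha=100.0)
        assert probability_of_connectivity(net, UNIT_DECAY) == pytest.approx(
            (9.0 + 16.0) / 10_000.0
        )

    def test_empty_network(self):
        net = make_network({}, [], landscape_area_ha=10.0)
        assert probability_of_connectivity(net, UNIT_DECAY) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        areas, edges, net = random_abstract_network(rng)
        expected = pc_oracle(areas, {(i, j): d for i, j, d in edges}, 1.0, 100.0)
        assert probability_of_connectivity(net, UNIT_DECAY) == pytest.approx(
            expected, rel=1e-12
        )

    def test_adding_edge_never_decreases_pc(self, rng):
        areas = {1: 2.0, 2: 3.0, 3: 4.0}
        edges = [(1, 2, 1.0)]
        base = probability_of_connectivity(make_network(areas, edges), UNIT_DECAY)
        more = probability_of_connectivity(
            make_network(areas, edges + [(2, 3, 0.5)]), UNIT_DECAY
        )
        assert more >= base


class TestDeltaPC:
    def test_single_patch_removal_destroys_everything(self):
        net = make_network({1: 5.0}, [])
        assert delta_pc(net, UNIT_DECAY)[1] == pytest.approx(100.0)

    def test_negligible_patch(self):
        net = make_network({1: 10.0, 2: 1e-9}, [])
        assert delta_pc(net, UNIT_DECAY)[2] == pytest.approx(0.0, abs=1e-12)

    def test_chain_matches_leave_one_out(self):
        areas = {i: float(i) for i in range(1, 6)}
        edges = [(i, i + 1, 0.4) for i in range(1, 5)]
        edge_map = {(i, j): d for i, j, d in edges}
        net = make_network(areas, edges, landscape_area_ha=200.0)
        dpc = delta_pc(net, UNIT_DECAY)
        pc_full = pc_oracle(areas, edge_map, 1.0, 200.0)
        for removed in areas:
            sub_areas = {k: v for k, v in areas.items() if k != removed}
            sub_edges = {e: d for e, d in edge_map.items() if removed not in e}
            pc_sub = pc_oracle(sub_areas, sub_edges, 1.0, 200.0)
            assert dpc[removed] == pytest.approx(100 * (pc_full - pc_sub) / pc_full, rel=1e-10)

    def test_bounds(self, rng):
        areas, edges, net = random_abstract_network(rng)
        for value in delta_pc(net, UNIT_DECAY).values():
            assert -1e-9 <= value <= 100.0 + 1e-9


class TestBCPC:
    def test_three_node_chain(self):
        net = make_network({1: 1.0, 2: 1.0, 3: 1.0}, [(1, 2, 1.0), (2, 3, 1.0)])
        scores = bc_pc(net, UNIT_DECAY)
        assert scores[2] == pytest.approx(math.exp(-2.0), rel=1e-12)
        assert scores[1] == 0.0 and scores[3] == 0.0

    def test_tree_leaves_score_zero(self, rng):
        areas = {i: float(rng.uniform(1, 5)) for i in range(1, 7)}
        edges = [(1, 2, 1.0), (1, 3, 0.5), (2, 4, 0.7), (2, 5, 0.2), (3, 6, 1.1)]
        scores = bc_pc(make_network(areas, edges), UNIT_DECAY)
        for leaf in (4, 5, 6):
            assert scores[leaf] == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        areas, edges, net = random_abstract_network(rng)
        expected = bcpc_oracle(areas, {(i, j): d for i, j, d in edges}, 1.0)
        scores = bc_pc(net, UNIT_DECAY)
        for node in areas:
            assert scores[node] == pytest.approx(expected[node], rel=1e-12, abs=1e-15)


class TestCurrentFlow:
    def test_two_node_single_resistor(self):
        net = make_network({1: 1.0, 2: 1.0}, [(1, 2, 2.0)])
        cf = current_flow(net)
        # each node participates in two groundings, carrying one unit each
        assert cf[1] == pytest.approx(2.0) and cf[2] == pytest.approx(2.0)

    def test_three_node_series_circuit(self):
        net = make_network({1: 1.0, 2: 1.0, 3: 1.0}, [(1, 2, 1.5), (2, 3, 4.0)])
        cf = current_flow(net)
        # hand-solved Kirchhoff: ends relay 1+2+1 units, middle 2+2+2
        assert cf[1] == pytest.approx(4.0, abs=1e-10)
        assert cf[2] == pytest.approx(6.0, abs=1e-10)
        assert cf[3] == pytest.approx(4.0, abs=1e-10)

    def test_invariant_under_conductance_scaling(self, rng):
        areas = {i: 1.0 for i in range(1, 6)}
        edges = [(1, 2, 1.0), (2, 3, 0.5), (3, 4, 2.0), (4, 5, 1.2), (2, 5, 0.8)]
        cf1 = current_flow(make_network(areas, edges))
        cf2 = current_flow(make_network(areas, [(i, j, 7.0 * d) for i, j, d in edges]))
        for node in areas:
            assert cf1[node] == pytest.approx(cf2[node], rel=1e-10)

    def test_isolated_node_carries_no_current(self):
        net = make_network({1: 1.0, 2: 1.0, 3: 1.0}, [(1, 2, 1.0)])
        assert current_flow(net)[3] == 0.0


class TestIIC:
    def test_isolated_patches_self_terms_only(self):
        net = make_network({1: 3.0, 2: 4.0}, [], landscape_area_ha=100.0)
        assert iic(net) == pytest.approx((9 + 16) / 10_000.0)
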