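import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from richclubnet.null_models import build_ensemble
from richclubnet.paths import (
    communication_cost,
    count_shortest_paths,
    cross_module_paths,
    degree_profile_along_paths,
    flow_asymmetry,
    rc_participation,
)
from richclubnet.richclub import classify_edges
from tests.conftest import make_net, random_digraph


def enumerate_all_shortest_paths(net):
    g = net.to_digraph()
    sigma, edge_use, total = {}, {}, 0
    for s, t in itertools.permutations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        sigma[(s, t)] = len(paths)
        total += len(paths)
        for p in paths:
            for u, v in zip(p[:-1], p[1:]):
                edge_use[(u, v)] = edge_use.get((u, v), 0) + 1
    return sigma, edge_use, total


class TestCounting:
    def test_grid_has_two_degenerate_routes(self, fixtures):
        ps = count_shortest_paths(fixtures["grid_2x2"])
        assert ps.sigma[0, 3] == 2

    def test_complete_digraph_total(self, fixtures):
        ps = count_shortest_paths(fixtures["complete_5"])
        assert ps.total_paths == 5 * 4

    def test_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            net = random_digraph(rng, n=6)
            ps = count_shortest_paths(net)
            sigma, edge_use, total = enumerate_all_shortest_paths(net)
            assert ps.total_paths == total
            for (s, t), v in sigma.items():
                assert ps.sigma[s, t] == v
            for e, (u, v) in enumerate(ps.edges):
                assert ps.edge_usage[e] == edge_use.get((u, v), 0)

    def test_usage_conservation(self, small_planted):
        """Sum of per-edge usage equals the summed length of all paths."""
        net, _ = small_planted
        ps = count_shortest_paths(net)
        lengths = (ps.sigma * np.where(ps.dist > 0, ps.dist, 0)).sum()
        assert ps.edge_usage.sum() == pytest.approx(lengths)

    def test_node_usage_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            net = random_digraph(rng, n=6)
            ps = count_shortest_paths(net)
            g = net.to_digraph()
            manual = np.zeros(net.n_nodes)
            for s, t in itertools.permutations(g.nodes, 2):
                try:
                    paths = list(nx.all_shortest_paths(g, s, t))
                except nx.NetworkXNoPath:
                    continue
                for p in paths:
                    for v in p[1:-1]:
                        manual[v] += 1
            assert np.allclose(ps.node_usage, manual)


class TestParticipation:
    def test_empty_club_zero_fractions(self, fixtures):
        res = rc_participation(fixtures["two_clique_bridge"], [])
        assert res.frac_touch_node == res.frac_travel_edge == 0.0

    def test_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(4, 8))
            net = random_digraph(rng, n=n, p=0.45)
            rc = set(int(x) for x in rng.choice(n, 2, replace=False))
            g = net.to_digraph()
            tot = touch = travel = 0
            for s, t in itertools.permutations(range(n), 2):
                if s in rc or t in rc:
                    continue
                try:
                    paths = list(nx.all_shortest_paths(g, s, t))
                except nx.NetworkXNoPath:
                    continue
                for p in paths:
                    tot += 1
                    touch += any(v in rc for v in p[1:-1])
                    travel += any(
                        u in rc and v in rc for u, v in zip(p[:-1], p[1:])
                    )
            res = rc_participation(net, rc)
            assert res.total_paths == tot
            assert res.touch_paths == touch
            assert res.travel_paths == travel

    def test_travel_bounded_by_touch(self, planted):
        net, truth = planted
        res = rc_participation(net, truth.rc_nodes)
        assert 0 < res.frac_travel_edge <= res.frac_touch_node < 1


class TestDegreeProfile:
    def test_flat_on_degree_regular_lattice(self):
        # directed circulant: every node -> next 3; degree-regular
        n = 30
        a = np.zeros((n, n), dtype=int)
        for i in range(n):
            for o in (1, 2, 3):
                a[i, (i + o) % n] = 1
        net = make_net(a)
        prof = degree_profile_along_paths(net, rc_nodes=[], lengths=(2, 3))
        for ell in (2, 3):
            medians = prof.median_degree[ell]
            assert np.allclose(medians, medians[0])

    def test_rises_then_falls_on_planted_network(self, planted):
        net, truth = planted
        prof = degree_profile_along_paths(
            net, truth.rc_nodes, lengths=(3, 4)
        )
        for ell in (3, 4):
            med = prof.median_degree[ell]
            interior = med[1:-1]
            assert interior.max() > med[0]
            assert interior.max() > med[-1]
            touch = prof.touch_prob[ell]
            assert touch[0] == touch[-1] == 0.0  # non-club endpoints
            assert touch[1:-1].max() > 0.1

    def test_position_counts_normalize_to_path_totals(self, small_planted):
        net, truth = small_planted
        prof = degree_profile_along_paths(net, truth.rc_nodes, lengths=(2, 3))
        for ell in (2, 3):
            counts = prof.node_position_counts[ell]
            for p in range(ell + 1):
                assert counts[p].sum() == pytest.approx(prof.n_paths[ell])


class TestFlowAsymmetry:
    def test_fully_reciprocal_network_balanced(self):
        rng = np.random.default_rng(5)
        a = (rng.random((14, 14)) < 0.35).astype(np.uint8)
        a = a | a.T
        np.fill_diagonal(a, 0)
        net = make_net(a)
        ens = build_ensemble(net, "randomized", 15, seed=1)
        fa = flow_asymmetry(net, [0, 1, 2], ens)
        assert np.allclose(fa.ratio, 0.0)

    def test_pure_entry_and_exit_boundaries(self):
        # two-node club: node 3 only absorbs paths (all feeders incoming,
        # internal hand-off to 4), node 4 only emits them
        a = np.zeros((6, 6), dtype=np.uint8)
        a[0, 3] = a[1, 3] = 1  # feeders into 3
        a[3, 4] = 1  # club edge
        a[4, 2] = a[4, 5] = 1  # feeders out of 4
        net = make_net(a)
        ens = build_ensemble(net, "randomized", 10, seed=2)
        fa = flow_asymmetry(net, [3, 4], ens)
        assert fa.ratio[list(fa.rc_nodes).index(3)] == 1.0
        assert fa.ratio[list(fa.rc_nodes).index(4)] == -1.0

    def test_ratio_bounds_and_frame(self, small_planted):
        net, truth = small_planted
        ens = build_ensemble(net, "randomized", 20, seed=3)
        fa = flow_asymmetry(net, truth.rc_nodes, ens)
        ok = ~np.isnan(fa.ratio)
        assert ((fa.ratio[ok] >= -1) & (fa.ratio[ok] <= 1)).all()
        frame = fa.as_frame(net)
        assert len(frame) == len(truth.rc_nodes)


class TestCommunicationCost:
    def test_unit_lengths_make_cost_track_usage(self, small_planted):
        net, truth = small_planted
        # place all nodes at distinct points on a unit-spaced line so
        # every edge has positive length; then use constant coordinates
        coords = pd.DataFrame(
            {"x": np.zeros(net.n_nodes), "y": 0.0, "z": 0.0},
            index=list(net.labels),
        )
        coords["x"] = 1.0  # all identical -> zero length, cost zero
        classes = classify_edges(net, truth.rc_nodes)
        cost = communication_cost(net, coords, classes)
        assert cost.per_edge.cost.sum() == 0.0
        # density shares still partition to 1
        assert sum(cost.class_density_share.values()) == pytest.approx(1.0)

    def test_club_edges_cost_share_exceeds_density_share(self, planted):
        net, truth = planted
        classes = classify_edges(net, truth.rc_nodes)
        cost = communication_cost(net, truth.coords, classes)
        assert cost.cost_over_density["rich_club"] > 1.5
        assert cost.cost_over_density["local"] < 1.0
        assert sum(cost.class_cost_share.values()) == pytest.approx(1.0)
        # planted club edges cross module clusters, hence span longer
        # distances than local edges (feeders carry no such guarantee
        # in the generator's geometry)
        tests = cost.tests.set_index(["comparison", "measure"]).p_value
        assert tests.loc[("rich_club > local", "length")] < 0.001
        assert tests.loc[("rich_club > local", "cost")] < 0.001

    def test_missing_coordinates_restrict_subnetwork(self, small_planted):
        net, truth = small_planted
        coords = truth.coords.iloc[: net.n_nodes // 2]
        classes = classify_edges(net, truth.rc_nodes)
        cost = communication_cost(net, coords, classes)
        assert cost.n_covered_nodes == net.n_nodes // 2
        covered = set(coords.index)
        assert set(cost.per_edge.source) <= covered
        assert set(cost.per_edge.target) <= covered

    def test_too_few_covered_nodes_rejected(self, small_planted):
        net, truth = small_planted
        classes = classify_edges(net, truth.rc_nodes)
        with pytest.raises(ValueError, match="coordinates"):
            communication_cost(net, truth.coords.iloc[:1], classes)


class TestCrossModule:
    def test_full_club_involves_every_path(self, small_planted):
        net, truth = small_planted
        table = cross_module_paths(
            net, truth.module_of, list(range(net.n_nodes))
        )
        overall = table[table.module_from == -1]
        assert overall.involved_fraction.iloc[0] == pytest.approx(1.0)

    def test_planted_club_involvement_substantial(self, planted):
        net, truth = planted
        table = cross_module_paths(net, truth.module_of, truth.rc_nodes)
        overall = table[table.module_from == -1].involved_fraction.iloc[0]
        assert 0.3 < overall < 1.0
        pairs = table[table.module_from >= 0]
        assert len(pairs) == 20  # ordered pairs of 5 modules
        assert ((pairs.involved_fraction >= 0)
                & (pairs.involved_fraction <= 1)).all()

    def test_single_module_partition_empty(self, small_planted):
        net, truth = small_planted
        table = cross_module_paths(
            net, np.zeros(net.n_nodes, dtype=int), truth.rc_nodes
        )
        overall = table[table.module_from == -1]
        assert overall.total_paths.iloc[0] == 0.0
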