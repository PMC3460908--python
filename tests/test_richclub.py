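import warnings

import numpy as np
import pytest

from richclubnet.network_core import degrees
from richclubnet.null_models import NullEnsemble, build_ensemble, randomize
from richclubnet.richclub import (
    classify_edges,
    fdr_correct,
    kcore_decompose,
    phi,
    rich_club_curve,
)
from tests.conftest import make_net, random_digraph


class TestPhi:
    def test_complete_digraph(self, fixtures):
        net = fixtures["complete_5"]
        # every node has total degree 8; any k < 8 leaves all nodes
        assert phi(net, 2) == 1.0

    def test_density_definition_by_hand(self):
        # two reciprocal hubs + 2 peripheral nodes; k threshold isolates hubs
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1  # hub dyad
        for h in (0, 1):
            for p in (2, 3):
                a[h, p] = a[p, h] = 1
        net = make_net(a)
        k = degrees(net).k
        assert k[0] == k[1] == 6 and k[2] == k[3] == 4
        # nodes with degree > 4: the two hubs; 2 of 2 ordered pairs wired
        assert phi(net, 4) == 1.0

    def test_too_few_qualifying_nodes(self, fixtures):
        with pytest.raises(ValueError, match="fewer than 2"):
            phi(fixtures["complete_5"], 8)

    def test_sweep_matches_direct_recomputation(self, small_planted):
        """Vectorized curve equals node-set density recomputed per k."""
        net, _ = small_planted
        ens = NullEnsemble([randomize(net, seed=1)], "randomized", 1, 10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = rich_club_curve(net, ens)
        for k, value in zip(res.k_values, res.phi):
            assert value == pytest.approx(phi(net, int(k)), abs=1e-12)


class TestFDR:
    def test_all_zero_all_survive(self):
        flags, _ = fdr_correct(np.zeros(5), q=0.05)
        assert flags.all()

    def test_all_one_none_survive(self):
        flags, _ = fdr_correct(np.ones(5), q=0.05)
        assert not flags.any()

    def test_hand_worked_step_up(self):
        # thresholds i*q/m = 0.0125, 0.025, 0.0375, 0.05:
        # p3 = 0.04 > 0.0375, so the step-up keeps exactly the first two
        flags, adjusted = fdr_correct([0.01, 0.02, 0.04, 0.8], q=0.05)
        assert flags.tolist() == [True, True, False, False]
        # adjusted p: min_{j>=i} m*p_j/j, monotone
        assert adjusted[0] == pytest.approx(0.04)
        assert adjusted[2] == pytest.approx(4 * 0.04 / 3)

    def test_hand_worked_all_survive(self):
        flags, _ = fdr_correct([0.001, 0.002, 0.003, 0.04], q=0.05)
        assert flags.all()


class TestRichClubCurve:
    def test_planted_club_significant_over_contiguous_range(self, planted):
        net, truth = planted
        ens = build_ensemble(net, "randomized", 200, seed=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = rich_club_curve(net, ens)
        sig_k = res.k_values[res.fdr_significant]
        assert sig_k.size > 0
        # the range covering the planted club is contiguous around the
        # club's degree bracket
        club_k = degrees(net).k[sorted(truth.rc_nodes)]
        assert sig_k.min() < club_k.min() <= sig_k.max()
        assert (res.phi_norm[res.fdr_significant] > 1).all()

    def test_levels_strictly_nested_with_degree_invariant(self, planted):
        net, _ = planted
        ens = build_ensemble(net, "randomized", 200, seed=41)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = rich_club_curve(net, ens)
        k = degrees(net).k
        assert len(res.levels) >= 2
        for j in range(len(res.levels) - 1):
            assert res.levels[j] < res.levels[j + 1]  # strict nesting
        for level, level_k in zip(res.levels, res.level_k):
            assert all(k[i] > level_k for i in level)

    def test_randomized_input_not_significant(self, small_planted):
        net, _ = small_planted
        rnet = randomize(net, seed=77)
        ens = build_ensemble(rnet, "randomized", 150, seed=78)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = rich_club_curve(rnet, ens)
        assert not res.fdr_significant.any()

    def test_requires_randomized_model(self, small_planted):
        net, _ = small_planted
        latt = build_ensemble(net, "latticized", 2, seed=0)
        with pytest.raises(ValueError, match="randomized"):
            rich_club_curve(net, latt)


class TestEdgeClassification:
    def test_empty_club_all_local(self, fixtures):
        net = fixtures["two_clique_bridge"]
        cls = classify_edges(net, [])
        assert cls.counts() == {
            "rich_club": 0, "feeder": 0, "local": net.n_edges
        }

    def test_full_club_all_rich(self, fixtures):
        net = fixtures["two_clique_bridge"]
        cls = classify_edges(net, range(net.n_nodes))
        assert cls.counts()["rich_club"] == net.n_edges

    def test_three_way_partition_exhaustive(self):
        rng = np.random.default_rng(4)
        net = random_digraph(rng, n=10, p=0.3)
        rc = {0, 1, 2}
        cls = classify_edges(net, rc)
        assert len(cls.class_of) == net.n_edges
        for (s, t), label in cls.class_of.items():
            inside = (s in rc) + (t in rc)
            assert label == {2: "rich_club", 1: "feeder", 0: "local"}[inside]


class TestKCore:
    def test_complete_reciprocal_graph_single_shell(self):
        n = 6
        net = make_net(np.ones((n, n), dtype=int) - np.eye(n, dtype=int))
        core = kcore_decompose(net)
        assert (core.core_level == 2 * (n - 1)).all()
        assert core.disintegration_k == 2 * (n - 1) + 1
        assert core.peak_core_size == n

    def test_core_level_bounded_by_degree(self, small_planted):
        net, _ = small_planted
        core = kcore_decompose(net)
        assert (core.core_level <= degrees(net).k).all()

    def test_club_survives_longest(self, planted):
        """Planted club members sit in the innermost surviving core."""
        net, truth = planted
        core = kcore_decompose(net)
        club = sorted(truth.rc_nodes)
        top_level = core.core_level.max()
        assert (core.core_level[club] >= np.percentile(
            core.core_level, 90
        )).all()
        assert core.core_level[club].max() == top_level

    def test_subshell_rank_recorded_at_disintegration(self, small_planted):
        net, _ = small_planted
        core = kcore_decompose(net)
        # every node detaches at the disintegration degree, in some pass
        assert (core.subshell_rank >= 1).all()
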