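import numpy as np

from richclubnet.motifs import (
    APEX_CLASSES,
    N_CLASSES,
    apex_ratio,
    brute_force_census,
    class_counts_networkx,
    exhaustive_star_size,
    largest_star,
    motif_library,
    motif_zscores,
    star_sizes,
    triad_census,
)
from richclubnet.null_models import NullEnsemble, build_ensemble
from richclubnet.smallworld import clustering_directed
from tests.conftest import make_net, random_digraph


class TestLibrary:
    def test_thirteen_connected_classes(self):
        lib = motif_library()
        assert len(lib) == N_CLASSES == 13
        assert sorted(lib.class_id) == list(range(1, 14))

    def test_apex_classes_join_unconnected_pairs(self):
        """Classes 4, 6, 9 have one node adjacent to two mutually
        unconnected nodes; 9 is the fully reciprocal apex."""
        lib = motif_library().set_index("class_id")
        assert set(lib.index[lib.is_apex_class]) == set(APEX_CLASSES)
        assert lib.loc[9, "census_name"] == "201"
        assert lib.loc[13, "census_name"] == "300"
        assert lib.loc[13, "n_edges"] == 6
        # edge-count grouping: 2,2,2 | 3,3,3,3 | 4,4,4,4 | 5 | 6
        assert lib.n_edges.tolist() == [2, 2, 2, 3, 3, 3, 3, 4, 4, 4, 4, 5, 6]


class TestCensus:
    def test_star_counts_only_motif_nine(self, fixtures):
        census = triad_census(fixtures["reciprocal_star_5"])
        expected = np.zeros(N_CLASSES + 1, dtype=int)
        expected[9] = 10  # all C(5,2) leaf pairs around the center
        assert np.array_equal(census.class_count, expected)
        assert census.node_apex_count[0, 9] == 10

    def test_cycle_is_single_cyclic_triad(self, fixtures):
        census = triad_census(fixtures["cycle_3"])
        assert census.class_count[7] == 1
        assert census.class_count.sum() == 1
        assert census.node_apex_count.sum() == 0

    def test_matches_brute_force_and_networkx(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            net = random_digraph(rng, n=int(rng.integers(3, 9)))
            c = triad_census(net)
            assert np.array_equal(c.class_count, brute_force_census(net))
            assert np.array_equal(c.class_count, class_counts_networkx(net))

    def test_participation_sums_to_three_per_instance(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            net = random_digraph(rng, n=7, p=0.4)
            c = triad_census(net)
            assert np.array_equal(
                c.node_participation.sum(axis=0), 3 * c.class_count
            )
            assert (c.node_apex_count <= c.node_participation).all()


class TestApexRatio:
    def test_star_center_and_leaf(self, fixtures):
        census = triad_census(fixtures["reciprocal_star_5"])
        assert apex_ratio(census, 0, classes=9) == 1.0
        assert apex_ratio(census, 1, classes=9) == 0.0

    def test_no_participation_gives_zero(self, fixtures):
        census = triad_census(fixtures["cycle_3"])
        assert apex_ratio(census, 0) == 0.0

    def test_club_apex_ratio_exceeds_background(self, planted):
        """Rich-club members dominate apex positions of motif 9 and have
        depressed clustering (the apex node joins unconnected pairs)."""
        net, truth = planted
        census = triad_census(net)
        club = sorted(truth.rc_nodes)
        rest = [i for i in range(net.n_nodes) if i not in truth.rc_nodes]
        club_ratio = np.mean([census.apex_ratio(i, classes=9) for i in club])
        rest_ratio = np.mean([census.apex_ratio(i, classes=9) for i in rest])
        assert club_ratio > 2 * rest_ratio
        clus = clustering_directed(net)
        assert clus[club].mean() < clus[rest].mean()


class TestZScores:
    def test_identical_ensemble_degenerate(self, fixtures):
        net = fixtures["two_clique_bridge"]
        same = NullEnsemble([net] * 3, "randomized", 0, 10)
        same_l = NullEnsemble([net] * 3, "latticized", 0, 10)
        z = motif_zscores(net, same, same_l)
        assert z.degenerate_random.all()
        assert z.z_vs_random.isna().all()

    def test_apex_motifs_enriched_versus_random(self, small_planted):
        net, _ = small_planted
        rand = build_ensemble(net, "randomized", 30, seed=9)
        latt = build_ensemble(net, "latticized", 30, seed=10)
        z = motif_zscores(net, rand, latt)
        assert (z.loc[list(APEX_CLASSES), "z_vs_random"] > 3).all()


class TestStars:
    def test_clean_star_fully_recovered(self, fixtures):
        star = largest_star(fixtures["reciprocal_star_5"], center=0)
        assert star.leaves == frozenset({1, 2, 3, 4, 5})

    def test_clique_neighbors_give_single_leaf(self):
        n = 5
        net = make_net(np.ones((n, n), dtype=int) - np.eye(n, dtype=int))
        assert largest_star(net, center=0).size == 1

    def test_no_reciprocal_neighbors_empty_star(self, fixtures):
        assert largest_star(fixtures["cycle_3"], center=0).size == 0

    def test_star_validity_invariants(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = random_digraph(rng, n=10, p=0.4)
            a = net.adjacency
            star = largest_star(net, center=0, seed=3)
            for leaf in star.leaves:
                assert a[0, leaf] and a[leaf, 0]
            for x in star.leaves:
                for y in star.leaves:
                    if x != y:
                        assert not a[x, y]

    def test_greedy_matches_exhaustive_on_small_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            net = random_digraph(rng, n=int(rng.integers(5, 12)), p=0.45)
            greedy = largest_star(net, center=0, n_restarts=20, seed=1).size
            assert greedy == exhaustive_star_size(net, center=0)

    def test_club_stars_larger_than_background(self, planted):
        from scipy.stats import mannwhitneyu

        net, truth = planted
        sizes = star_sizes(net, n_restarts=5, seed=0)
        club = sorted(truth.rc_nodes)
        rest = [i for i in range(net.n_nodes) if i not in truth.rc_nodes]
        assert np.median(sizes[club]) > np.median(sizes[rest])
        p = mannwhitneyu(sizes[club], sizes[rest],
                         alternative="greater").pvalue
        assert p < 0.001
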