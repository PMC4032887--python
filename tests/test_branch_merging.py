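import numpy as np
import pytest

from neurotrace.branch_merging import (
    MergeCluster,
    TerminalPoint,
    bell_number,
    cluster_terminals,
    compute_cluster_features,
    dismantle_trace,
    enumerate_scenarios,
    limit_cluster_sizes,
    normalize_within_cluster,
    scenario_features,
    set_partitions,
)
from conftest import make_y_trace


def tp(pos, tangent=(1, 0, 0), branch_id=0, intensity=0.5, caliber=1.0):
    t = np.array(tangent, dtype=float)
    return TerminalPoint(branch_id, np.array(pos, dtype=float),
                         t / np.linalg.norm(t), intensity, caliber)


def make_cluster(terminals):
    cl = MergeCluster(list(terminals))
    enumerate_scenarios(cl)
    return cl


class TestScenarioEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 2), (3, 5), (4, 15), (5, 52)])
    def test_counts_match_bell_numbers(self, n, count):
        cl = make_cluster([tp((i, 0, 0), branch_id=i) for i in range(n)])
        assert len(cl.scenarios) == count
        assert bell_number(n) == count

    def test_bell_recurrence_oracle_up_to_8(self):
        # oracle: direct enumeration vs the recurrence B(n+1) = sum C(n,k) B(k)
        for n in range(1, 9):
            assert len(list(set_partitions(n))) == bell_number(n)

    def test_partitions_cover_and_are_disjoint(self):
        for part in set_partitions(4):
            flat = sorted(i for block in part for i in block)
            assert flat == [0, 1, 2, 3]

    def test_ordering_is_canonical_and_deterministic(self):
        a = list(set_partitions(4))
        b = list(set_partitions(4))
        assert a == b
        assert a[0] == ((0, 1, 2, 3),)  # all-merged comes first (RGS 0000)

    def test_too_small_cluster_rejected(self):
        cl = MergeCluster([tp((0, 0, 0))])
        with pytest.raises(ValueError):
            enumerate_scenarios(cl)

    def test_oversized_cluster_refused_with_guidance(self):
        cl = MergeCluster([tp((i, 0, 0), branch_id=i) for i in range(9)])
        with pytest.raises(ValueError, match="max_terminals"):
            enumerate_scenarios(cl)

    def test_oversized_cluster_split_by_rethresholding(self):
        # two tight knots of 5, 8 units apart: one 10-point cluster at
        # linkage 10 that splits into two 5-point clusters
        terminals = [tp((0.1 * i, 0, 0), branch_id=i) for i in range(5)]
        terminals += [tp((8 + 0.1 * i, 0, 0), branch_id=5 + i) for i in range(5)]
        clusters = cluster_terminals(terminals, 10.0)
        assert [c.n for c in clusters] == [10]
        split = limit_cluster_sizes(clusters, 10.0, cap=8)
        assert sorted(c.n for c in split) == [5, 5]


class TestClustering:
    def test_pair_below_threshold(self):
        clusters = cluster_terminals([tp((0, 0, 0)), tp((5, 0, 0), branch_id=1)], 10.0)
        assert len(clusters) == 1 and clusters[0].n == 2

    def test_pair_above_threshold_gives_no_clusters(self):
        clusters = cluster_terminals([tp((0, 0, 0)), tp((11, 0, 0), branch_id=1)], 10.0)
        assert clusters == []

    def test_single_linkage_chains(self):
        # A-B-C at 8 apart; |AC| = 16 > threshold but single linkage joins
        pts = [tp((0, 0, 0)), tp((8, 0, 0), branch_id=1), tp((16, 0, 0), branch_id=2)]
        clusters = cluster_terminals(pts, 10.0)
        assert len(clusters) == 1 and clusters[0].n == 3
        # brute-force oracle: connected components of the thresholded graph
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(3))
        for i in range(3):
            for j in range(i + 1, 3):
                if np.linalg.norm(pts[i].position - pts[j].position) <= 10.0:
                    g.add_edge(i, j)
        assert nx.number_connected_components(g) == 1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            cluster_terminals([], 0.0)


class TestFeatures:
    def test_all_singletons_scenario(self):
        cl = make_cluster([tp((i * 3, 0, 0), branch_id=i) for i in range(3)])
        sc = [s for s in cl.scenarios if all(len(b) == 1 for b in s.partition)][0]
        x = scenario_features(sc, cl)
        np.testing.assert_allclose(x[:8], 0.0)
        assert x[8] == 3

    def test_collinear_abutting_endpoints(self):
        # facing endpoints: outward tangents opposite, zero overrun/offset
        a = tp((0, 0, 0), tangent=(1, 0, 0), branch_id=0)
        b = tp((2, 0, 0), tangent=(-1, 0, 0), branch_id=1)
        cl = make_cluster([a, b])
        sc = [s for s in cl.scenarios if any(len(bl) == 2 for bl in s.partition)][0]
        x = scenario_features(sc, cl)
        assert x[0] == pytest.approx(2.0)  # distance
        assert x[1] == pytest.approx(0.0)  # overrun
        assert x[2] == pytest.approx(0.0)  # offset
        assert x[3] == pytest.approx(1.0)  # alignment -u_a.u_b
        assert x[8] == 0

    def test_crossing_correct_pairing_has_higher_alignment(self):
        # X crossing of two straight axons: four endpoints at the center,
        # correct pairing keeps each axon straight; the "stolen branch"
        # pairing bends 90 degrees
        e = [tp((-1, 0, 0), tangent=(1, 0, 0), branch_id=0),
             tp((1, 0, 0), tangent=(-1, 0, 0), branch_id=1),
             tp((0, -1, 0), tangent=(0, 1, 0), branch_id=2),
             tp((0, 1, 0), tangent=(0, -1, 0), branch_id=3)]
        cl = make_cluster(e)
        feats = {s.rgs(): scenario_features(s, cl) for s in cl.scenarios}
        correct = feats["0011"]  # {0,1}{2,3}: straight-through pairing
        stolen = feats["0101"]  # {0,2}{1,3}: right-angle merges
        assert correct[3] > stolen[3]

    def test_rigid_motion_invariance_of_geometric_features(self, rng):
        pts = [tp(rng.uniform(0, 5, 3), tangent=rng.normal(size=3), branch_id=i,
                  intensity=rng.uniform(), caliber=rng.uniform(0.5, 2))
               for i in range(3)]
        cl = make_cluster(pts)
        x0 = np.array([scenario_features(s, cl) for s in cl.scenarios])
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-10, 10, 3)
        moved = [TerminalPoint(p.branch_id, q @ p.position + shift, q @ p.tangent,
                               p.mean_intensity, p.mean_caliber) for p in pts]
        cl2 = make_cluster(moved)
        x1 = np.array([scenario_features(s, cl2) for s in cl2.scenarios])
        for col in (0, 1, 2, 3, 7, 8):
            np.testing.assert_allclose(x1[:, col], x0[:, col], atol=1e-9)

    def test_uniform_intensity_offset_leaves_intensity_feature(self, rng):
        pts = [tp(rng.uniform(0, 5, 3), branch_id=i, intensity=rng.uniform())
               for i in range(3)]
        cl = make_cluster(pts)
        x0 = np.array([scenario_features(s, cl) for s in cl.scenarios])
        shifted = [TerminalPoint(p.branch_id, p.position, p.tangent,
                                 p.mean_intensity + 0.17, p.mean_caliber) for p in pts]
        cl2 = make_cluster(shifted)
        x1 = np.array([scenario_features(s, cl2) for s in cl2.scenarios])
        np.testing.assert_allclose(x1[:, 4], x0[:, 4], atol=1e-12)


class TestSubtractiveNormalization:
    def test_two_scenario_cluster_gives_one_delta(self):
        cl = make_cluster([tp((0, 0, 0)), tp((2, 0, 0), branch_id=1)])
        compute_cluster_features(cl)
        cl.label = 0
        dx = normalize_within_cluster(cl)
        assert dx.shape == (1, 9)

    def test_delta_counts_and_comparison_total(self):
        # m = total number of scenarios minus number of clusters
        clusters = []
        for n in (2, 3, 4):
            cl = make_cluster([tp((i * 2.0, 0, 0), branch_id=i) for i in range(n)])
            compute_cluster_features(cl)
            cl.label = 1
            clusters.append(cl)
        total = sum(len(normalize_within_cluster(cl)) for cl in clusters)
        assert total == (2 + 5 + 15) - 3

    def test_correct_scenario_delta_is_excluded(self):
        cl = make_cluster([tp((0, 0, 0)), tp((2, 0, 0), branch_id=1)])
        compute_cluster_features(cl)
        cl.label = 1
        dx = normalize_within_cluster(cl)
        assert not np.allclose(dx, 0)

    def test_additive_constant_cancels(self):
        cl = make_cluster([tp((i * 2.0, 0, 0), branch_id=i) for i in range(3)])
        compute_cluster_features(cl)
        cl.label = 0
        dx0 = normalize_within_cluster(cl)
        for s in cl.scenarios:
            s.features = s.features + 3.7  # per-cluster additive offset
        dx1 = normalize_within_cluster(cl)
        np.testing.assert_allclose(dx1, dx0, atol=1e-12)

    def test_unlabeled_cluster_rejected(self):
        cl = make_cluster([tp((0, 0, 0)), tp((2, 0, 0), branch_id=1)])
        compute_cluster_features(cl)
        with pytest.raises(ValueError):
            normalize_within_cluster(cl)


class TestDismantle:
    def test_y_trace_dismantles_into_three_free_branches(self):
        import networkx as nx

        t = make_y_trace()
        disconnected, terminals = dismantle_trace(t)
        assert nx.number_connected_components(disconnected.graph) == 3
        assert len(terminals) == 6
        # three duplicated endpoints at the former junction position
        at_center = [tp_ for tp_ in terminals
                     if np.linalg.norm(tp_.position) < 1e-9]
        assert len(at_center) == 3

    def test_tangents_point_outward(self):
        t = make_y_trace()
        _, terminals = dismantle_trace(t)
        for term in terminals:
            if np.linalg.norm(term.position) > 1e-9:  # free arm end
                u = term.position / np.linalg.norm(term.position)
                assert np.dot(term.tangent, u) > 0.9
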