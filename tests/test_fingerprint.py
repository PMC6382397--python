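import math

import numpy as np
import pytest

from ethosleep import (
    BehaviorDistribution,
    FingerprintDistanceMatrix,
    SimConfig,
    behavior_distribution,
    bhattacharyya,
    pairwise_distance,
    score_ethogram,
    simulate_fly,
    ternary_trajectory,
    upgma,
)
from ethosleep.fingerprint import BD_EPS, N_INTERVALS, TERNARY_VERTICES


def _uniform_dist(animal_id="u"):
    return BehaviorDistribution(animal_id, np.full((N_INTERVALS, 3), 1 / 3))


class TestBehaviorDistribution:
    def test_all_quiescent_fly(self):
        states = np.zeros(1440, dtype=int)
        d = behavior_distribution(states)
        np.testing.assert_allclose(d.p[:, 0], 1.0)
        np.testing.assert_allclose(d.p[:, 1:], 0.0)

    def test_cycling_states_give_uniform_distribution(self):
        states = np.tile([0, 1, 2], 480)
        d = behavior_distribution(states)
        np.testing.assert_allclose(d.p, 1 / 3)

    def test_matches_per_interval_counting_oracle(self):
        eth = score_ethogram(simulate_fly(SimConfig(seed=6, duration_h=48)))
        d = behavior_distribution(eth.minute_states, eth.minute_t)
        # direct counting per quarter-hour
        minute_zt_bin = (np.arange(len(eth.minute_states)) % 1440) // 15
        for b in (0, 17, 95):
            sel = minute_zt_bin == b
            for s in range(3):
                expect = np.mean(eth.minute_states[sel] == s)
                assert d.p[b, s] == pytest.approx(expect)

    def test_incomplete_day_rejected(self):
        with pytest.raises(ValueError, match="full days"):
            behavior_distribution(np.zeros(100, dtype=int))


class TestBhattacharyya:
    def test_identical_distributions(self):
        p = np.array([0.2, 0.3, 0.5])
        bc, bd = bhattacharyya(p, p)
        assert bc == pytest.approx(1.0) and bd == pytest.approx(0.0)

    def test_disjoint_supports_capped(self):
        bc, bd = bhattacharyya([1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
        assert bc == 0.0
        assert bd == pytest.approx(-math.log(BD_EPS))

    def test_hand_computed_example(self):
        p, q = [0.25, 0.25, 0.5], [0.5, 0.25, 0.25]
        bc, bd = bhattacharyya(p, q)
        expect_bc = math.sqrt(0.125) + 0.25 + math.sqrt(0.125)
        assert bc == pytest.approx(expect_bc)
        assert bd == pytest.approx(-math.log(expect_bc))

    def test_divergence_not_metric(self):
        # symmetric with zero self-distance, but the triangle inequality
        # fails: through the uniform midpoint, two small hops beat the
        # direct (capped) distance between disjoint vertices
        p, q, r = [1.0, 0.0, 0.0], [1 / 3, 1 / 3, 1 / 3], [0.0, 1.0, 0.0]
        d_pq = bhattacharyya(p, q)[1]
        d_qr = bhattacharyya(q, r)[1]
        d_pr = bhattacharyya(p, r)[1]
        assert bhattacharyya(p, q)[1] == bhattacharyya(q, p)[1]
        assert d_pr > d_pq + d_qr


class TestPairwiseDistance:
    def test_identical_animals_distance_zero(self):
        mat = pairwise_distance([_uniform_dist("a"), _uniform_dist("b")])
        assert mat.d[0, 1] == pytest.approx(0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        dists = []
        for i in range(5):
            raw = rng.dirichlet([2, 2, 2], N_INTERVALS)
            dists.append(BehaviorDistribution(f"a{i}", raw))
        mat = pairwise_distance(dists)
        for i in range(5):
            for j in range(5):
                acc = 0.0
                for t in range(N_INTERVALS):
                    bc = sum(
                        math.sqrt(dists[i].p[t, x] * dists[j].p[t, x]) for x in range(3)
                    )
                    acc += -math.log(max(min(bc, 1.0), BD_EPS))
                assert mat.d[i, j] == pytest.approx(acc / N_INTERVALS, abs=1e-12)

    def test_permutation_consistency(self):
        rng = np.random.default_rng(4)
        dists = [
            BehaviorDistribution(f"a{i}", rng.dirichlet([1, 1, 1], N_INTERVALS))
            for i in range(4)
        ]
        m1 = pairwise_distance(dists)
        m2 = pairwise_distance(dists[::-1])
        perm = np.arange(4)[::-1]
        np.testing.assert_allclose(m2.d, m1.d[np.ix_(perm, perm)], atol=1e-12)

    def test_interval_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.dirichlet([1, 2, 3], N_INTERVALS)
        b = rng.dirichlet([3, 2, 1], N_INTERVALS)
        perm = rng.permutation(N_INTERVALS)
        d1 = pairwise_distance(
            [BehaviorDistribution("a", a), BehaviorDistribution("b", b)]
        ).d[0, 1]
        d2 = pairwise_distance(
            [BehaviorDistribution("a", a[perm]), BehaviorDistribution("b", b[perm])]
        ).d[0, 1]
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestUpgma:
    def test_two_leaves(self):
        mat = FingerprintDistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        dend = upgma(mat)
        assert dend.merges == [(0, 1, 1.0, 2)]

    def test_ultrametric_input_recovered_exactly(self):
        # cophenetic distances of a known ultrametric tree
        d = np.array(
            [
                [0.0, 2.0, 6.0, 6.0],
                [2.0, 0.0, 6.0, 6.0],
                [6.0, 6.0, 0.0, 4.0],
                [6.0, 6.0, 4.0, 0.0],
            ]
        )
        dend = upgma(FingerprintDistanceMatrix(list("abcd"), d))
        np.testing.assert_allclose(dend.cophenetic(), d, atol=1e-12)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        for seed in range(4):
            rng = np.random.default_rng(seed)
            a = rng.uniform(1, 10, (6, 6))
            d = (a + a.T) / 2.0
            np.fill_diagonal(d, 0.0)
            dend = upgma(FingerprintDistanceMatrix([f"L{i}" for i in range(6)], d))
            _, coph = cophenet(linkage(squareform(d), method="average"), squareform(d))
            np.testing.assert_allclose(squareform(dend.cophenetic()), coph, atol=1e-9)

    def test_non_finite_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            upgma(FingerprintDistanceMatrix(["a", "b"], d))

    def test_two_cluster_cut(self):
        d = np.array(
            [
                [0.0, 1.0, 8.0, 8.0],
                [1.0, 0.0, 8.0, 8.0],
                [8.0, 8.0, 0.0, 1.0],
                [8.0, 8.0, 1.0, 0.0],
            ]
        )
        dend = upgma(FingerprintDistanceMatrix(list("abcd"), d))
        cut = dend.cut(2)
        assert cut["a"] == cut["b"] != cut["c"] == cut["d"]


class TestTernary:
    def test_vertices_and_centroid(self):
        p = np.zeros((N_INTERVALS, 3))
        p[:, 0] = 1.0
        xy = ternary_trajectory(BehaviorDistribution("v", p))
        np.testing.assert_allclose(xy, np.tile(TERNARY_VERTICES[0], (N_INTERVALS, 1)))
        xy = ternary_trajectory(_uniform_dist())
        np.testing.assert_allclose(
            xy, np.tile(TERNARY_VERTICES.mean(axis=0), (N_INTERVALS, 1)), atol=1e-12
        )

    def test_round_trip_inverse_barycentric(self):
        rng = np.random.default_rng(6)
        p = rng.dirichlet([2, 3, 4], N_INTERVALS)
        xy = ternary_trajectory(BehaviorDistribution("r", p))
        # invert: barycentric coordinates w.r.t. the triangle
        M = np.vstack([TERNARY_VERTICES.T, np.ones(3)])
        recovered = np.linalg.solve(M, np.vstack([xy.T, np.ones(len(xy))])).T
        np.testing.assert_allclose(recovered, p, atol=1e-9)
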