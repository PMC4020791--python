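import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from pepwords import (
    MdsMethod,
    Metric,
    VectorMode,
    lda_separation,
    mds_embed,
    multigroup_test,
    permutation_test,
    vector_distance_matrix,
)
from pepwords.word_statistics import RepeatVector


def _vec(bins, gid="v", mode=VectorMode.DISTANCE, norm=100):
    return RepeatVector(gid, np.array(bins, dtype=float), mode, norm)


class TestDistanceMatrix:
    def test_identical_vectors_give_zero_matrix(self):
        vs = [_vec([0, 0, 1.0, 2.0], gid=f"g{i}") for i in range(4)]
        d = vector_distance_matrix(vs)
        assert not d.any()

    def test_one_hot_euclidean_hand_value(self):
        vs = [
            _vec([0, 0, 3.0, 0.0], "a"),
            _vec([0, 0, 0.0, 3.0], "b"),
            _vec([0, 0, 0.0, 0.0], "c"),
        ]
        d = vector_distance_matrix(vs, Metric.EUCLIDEAN)
        assert d[0, 1] == pytest.approx(3.0 * np.sqrt(2))
        assert d[0, 2] == pytest.approx(3.0)

    def test_symmetry_zero_diagonal_triangle_inequality(self):
        rng = np.random.default_rng(0)
        vs = [
            _vec(np.concatenate([[0, 0], rng.random(8)]), gid=f"g{i}")
            for i in range(6)
        ]
        d = vector_distance_matrix(vs)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        n = len(vs)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_mixed_modes_rejected(self):
        vs = [
            _vec([0, 0, 1.0], "a"),
            _vec([0, 0, 1.0], "b", mode=VectorMode.COUNT),
            _vec([0, 0, 1.0], "c"),
        ]
        with pytest.raises(ValueError, match="mixed"):
            vector_distance_matrix(vs)


class TestMds:
    def test_classical_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(1)
        points = rng.normal(size=(12, 2))
        d = squareform(pdist(points))
        coords = mds_embed(d, k=2, method=MdsMethod.CLASSICAL)
        d2 = squareform(pdist(coords))
        assert np.allclose(d, d2, atol=1e-6)

    def test_equilateral_triangle(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        coords = mds_embed(d, k=2)
        d2 = squareform(pdist(coords))
        assert np.allclose(d2, d, atol=1e-9)

    def test_nonmetric_seeded_determinism(self):
        rng = np.random.default_rng(2)
        d = squareform(pdist(rng.normal(size=(10, 3))))
        a = mds_embed(d, k=2, method=MdsMethod.NONMETRIC, seed=5)
        b = mds_embed(d, k=2, method=MdsMethod.NONMETRIC, seed=5)
        assert np.array_equal(a, b)

    def test_k_must_be_below_n(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            mds_embed(d, k=3)


class TestLda:
    def test_isotropic_translated_clouds(self):
        """Two isotropic clouds offset by delta along e1: the Fisher axis is
        +-e1 and the separation is the offset."""
        rng = np.random.default_rng(3)
        delta = 4.0
        a = rng.normal(0, 0.3, size=(200, 2))
        b = a + np.array([delta, 0.0])
        x = np.vstack([a, b])
        y = np.array(["a"] * 200 + ["b"] * 200)
        w, sep = lda_separation(x, y)
        assert abs(abs(w[0]) - 1.0) < 0.02
        assert sep == pytest.approx(delta, rel=0.02)

    def test_random_labels_give_small_separation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(100, 2))
        y = rng.permutation(np.array(["a"] * 50 + ["b"] * 50))
        _, sep = lda_separation(x, y)
        assert sep < np.std(x)  # tiny relative to within-group spread

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 2))
        y = np.array(["a"] * 15 + ["b"] * 15)
        _, s1 = lda_separation(x, y)
        _, s2 = lda_separation(x, np.where(y == "a", "b", "a"))
        assert s1 == pytest.approx(s2)

    def test_rotation_invariance_of_separation(self):
        """Fisher separation is equivariant under rigid rotation/reflection of
        the embedding."""
        rng = np.random.default_rng(6)
        x = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(2, 1, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        theta = 1.234
        q = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        _, s1 = lda_separation(x, y)
        _, s2 = lda_separation(x @ q, y)
        assert s1 == pytest.approx(s2, rel=1e-8)

    def test_small_class_rejected(self):
        x = np.zeros((4, 2))
        with pytest.raises(ValueError):
            lda_separation(x, np.array(["a", "a", "a", "b"]))


class TestPermutationTest:
    def test_perfectly_separated_clusters_reach_floor_p(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(10, 0.1, size=(10, 2))  # planted offset of ~100 sigma
        x = np.vstack([a, b])
        y = np.array(["a"] * 10 + ["b"] * 10)
        res = permutation_test(x, y, m_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_value_never_zero_and_bounded(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(12, 2))
        y = np.array(["a"] * 6 + ["b"] * 6)
        res = permutation_test(x, y, m_permutations=99, seed=2)
        assert 1 / 100 <= res.p_value <= 1.0
        assert len(res.null_separations) == 99

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(16, 2))
        y = np.array(["a"] * 8 + ["b"] * 8)
        r1 = permutation_test(x, y, m_permutations=200, seed=3)
        r2 = permutation_test(x, y, m_permutations=200, seed=3)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_separations, r2.null_separations)

    def test_null_p_values_roughly_uniform(self):
        """Labels independent of coordinates: p-values follow the uniform
        distribution (Kolmogorov-Smirnov check over replicates)."""
        from scipy import stats

        rng = np.random.default_rng(10)
        pvals = []
        y = np.array(["a"] * 10 + ["b"] * 10)
        for _ in range(100):
            x = rng.normal(size=(20, 2))
            seed = int(rng.integers(2**31))
            pvals.append(permutation_test(x, y, m_permutations=199, seed=seed).p_value)
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 1.36 / np.sqrt(len(pvals)) + 0.05  # 5% critical value + slack

    def test_mrpp_statistic_alternative(self):
        from pepwords.group_discrimination import SeparationStatistic

        rng = np.random.default_rng(11)
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(5, 0.1, size=(10, 2))
        x = np.vstack([a, b])
        y = np.array(["a"] * 10 + ["b"] * 10)
        res = permutation_test(
            x, y, m_permutations=499, seed=4, statistic=SeparationStatistic.MRPP
        )
        assert res.p_value <= 0.01

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.zeros((6, 2)), np.array(["a"] * 3 + ["b"] * 3), 0)


class TestMultigroup:
    def _square_corners(self, rng, spread=0.05, n=5):
        centers = {"q1": (0, 0), "q2": (0, 3), "q3": (3, 0), "q4": (3, 3)}
        xs, ys = [], []
        for g, c in centers.items():
            xs.append(rng.normal(0, spread, size=(n, 2)) + np.array(c))
            ys += [g] * n
        return np.vstack(xs), np.array(ys)

    def test_identical_groups_near_zero_separation(self):
        rng = np.random.default_rng(12)
        block = rng.normal(size=(5, 2))
        x = np.vstack([block] * 4)
        y = np.array(sum([[g] * 5 for g in "abcd"], []))
        res = multigroup_test(x, y, m_permutations=199, seed=5)
        assert all(s < 1e-9 for s in res.pairwise_separation.values())

    def test_square_corner_groups_all_significant(self):
        rng = np.random.default_rng(13)
        x, y = self._square_corners(rng)
        res = multigroup_test(x, y, m_permutations=999, seed=6)
        assert all(p <= 0.02 for p in res.pairwise_p.values())
        assert res.omnibus_p <= 0.002

    def test_symmetric_accessors(self):
        rng = np.random.default_rng(14)
        x, y = self._square_corners(rng)
        res = multigroup_test(x, y, m_permutations=99, seed=7)
        assert res.separation("q1", "q2") == res.separation("q2", "q1")
        assert res.p("q3", "q4") == res.p("q4", "q3")

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            multigroup_test(np.zeros((4, 2)), np.array(["a"] * 4), 10)
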