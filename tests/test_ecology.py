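import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest

from mbfuse.ecology import (DistanceMatrix, alpha_diversity, bray_curtis,
                            intragroup_distances, pcoa, permanova)
from _helpers import make_table


def euclidean_dm(points):
    d = squareform(pdist(points))
    return DistanceMatrix([f"s{i}" for i in range(len(points))], d)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

class TestAlphaDiversity:
    @pytest.mark.parametrize("counts, metric, expected", [
        ([10, 10, 10, 10], "shannon", 2.0),       # uniform over 4, base 2
        ([7, 0, 0], "simpson", 0.0),              # single taxon
        ([1, 1, 2, 3, 4], "chao1", 5.5),          # S=5, F1=2, F2=1
    ])
    def test_closed_forms(self, counts, metric, expected):
        assert alpha_diversity(counts, metric) == pytest.approx(expected)

    def test_shannon_maximal_at_uniform(self, rng):
        k = 6
        uniform = alpha_diversity([5] * k, "shannon")
        for _ in range(20):
            skewed = rng.integers(1, 100, k)
            assert alpha_diversity(skewed, "shannon") <= uniform + 1e-12

    def test_simpson_range_and_chao1_lower_bound(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 30, 12)
            if counts.sum() == 0:
                continue
            s = alpha_diversity(counts, "simpson")
            assert 0 <= s < 1
            c = alpha_diversity(counts, "chao1")
            assert c >= (counts > 0).sum()

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0], "shannon")

    def test_chao1_requires_integers(self):
        with pytest.raises(ValueError, match="integer"):
            alpha_diversity([1.5, 2.0], "chao1")


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

class TestBrayCurtis:
    def test_identical_rows_distance_zero(self):
        dm = bray_curtis(make_table([[1, 2, 3], [1, 2, 3]]))
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_supports_distance_one(self):
        dm = bray_curtis(make_table([[2, 0], [0, 2]]))
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        dm = bray_curtis(make_table([[1, 1], [1, 3]]))
        assert dm.data[0, 1] == pytest.approx(1 / 3)

    def test_range_and_feature_permutation_invariance(self, rng):
        X = rng.integers(0, 40, size=(6, 10)).astype(float) + 1
        d1 = bray_curtis(make_table(X)).data
        assert (d1 >= 0).all() and (d1 <= 1).all()
        perm = rng.permutation(10)
        d2 = bray_curtis(make_table(X[:, perm])).data
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_matches_definition(self, rng):
        X = rng.integers(0, 30, size=(4, 7)).astype(float) + 1
        dm = bray_curtis(make_table(X))
        for i, j in itertools.combinations(range(4), 2):
            expected = 1 - 2 * np.minimum(X[i], X[j]).sum() / (X[i].sum() + X[j].sum())
            assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class TestPCoA:
    def test_equilateral_triangle_has_two_equal_axes(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d), k=2)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_round_trip_of_planted_2d_points(self, rng):
        pts = rng.normal(size=(5, 2))
        res = pcoa(euclidean_dm(pts), k=2)
        got = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(got, squareform(pdist(pts)), atol=1e-8)

    def test_variance_proportions_bounded(self, rng):
        pts = rng.normal(size=(8, 4))
        res = pcoa(euclidean_dm(pts), k=3)
        assert (res.proportions >= 0).all()
        assert res.proportions.sum() <= 1 + 1e-12
        assert np.all(np.diff(res.proportions) <= 1e-12)

    def test_k_too_large_rejected(self, rng):
        dm = euclidean_dm(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError):
            pcoa(dm, k=4)

    def test_agrees_with_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(7, 3))
        dm = euclidean_dm(pts)
        ours = pcoa(dm, k=3).coordinates.to_numpy()
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.data, ids=dm.ids)).samples.to_numpy()[:, :3]
        np.testing.assert_allclose(np.abs(ours), np.abs(ref), atol=1e-8)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def oracle_pseudo_f(d, labels):
    """Independent pseudo-F: definitional sums over pairs."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for idx in groups:
        ss_w += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    g = len(groups)
    return ((ss_t - ss_w) / (g - 1)) / (ss_w / (n - g))


class TestPermanova:
    def test_exhaustive_enumeration_on_n6(self, rng):
        pts = rng.normal(size=(6, 2))
        pts[:3] += 2.0
        dm = euclidean_dm(pts)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = permanova(dm, labels, n_perm=999, seed=0)
        assert res.exhaustive and res.n_permutations == 20
        assert res.pseudo_f == pytest.approx(oracle_pseudo_f(dm.data, labels))
        # oracle p: enumerate all 20 assignments
        fs = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(combo)] = "a"
            fs.append(oracle_pseudo_f(dm.data, lab))
        p_oracle = np.mean(np.array(fs) >= res.pseudo_f - 1e-12)
        assert res.p_value == pytest.approx(p_oracle)

    def test_duplicated_coordinates_give_unit_p(self, rng):
        pts = rng.normal(size=(3, 2))
        dm = euclidean_dm(np.vstack([pts, pts]))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(dm, labels)
        assert res.p_value >= 0.5  # observed F is in the bulk of the null

    def test_null_p_values_uniform(self, rng):
        ps = []
        for _ in range(500):
            pts = rng.normal(size=(14, 3))
            labels = np.array(["a"] * 7 + ["b"] * 7)
            res = permanova(euclidean_dm(pts), labels, n_perm=99,
                            seed=int(rng.integers(2 ** 31)))
            ps.append(res.p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_separated_clusters_attain_minimum_p(self, rng):
        pts = rng.normal(size=(20, 2))
        pts[:10] += 50.0
        labels = np.array(["a"] * 10 + ["b"] * 10)
        res = permanova(euclidean_dm(pts), labels, n_perm=999, seed=1)
        assert not res.exhaustive
        assert res.p_value == pytest.approx(1 / 1000)

    def test_label_renaming_invariance(self, rng):
        pts = rng.normal(size=(12, 2))
        dm = euclidean_dm(pts)
        l1 = np.array(["x"] * 6 + ["y"] * 6)
        l2 = np.array(["y"] * 6 + ["x"] * 6)
        assert (permanova(dm, l1, n_perm=99, seed=5).pseudo_f
                == pytest.approx(permanova(dm, l2, n_perm=99, seed=5).pseudo_f))

    def test_singleton_group_rejected(self, rng):
        dm = euclidean_dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match=">= 2 samples"):
            permanova(dm, np.array(["a", "a", "a", "a", "b"]))

    def test_agrees_with_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(16, 3))
        pts[:8, 0] += 1.0
        dm = euclidean_dm(pts)
        labels = ["a"] * 8 + ["b"] * 8
        ours = permanova(dm, np.array(labels), n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, ids=dm.ids), grouping=labels,
            permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"])


# ---------------------------------------------------------------------------
# intragroup distances
# ---------------------------------------------------------------------------

class TestIntragroupDistances:
    def test_group_of_three_yields_three_distances(self, rng):
        dm = euclidean_dm(rng.normal(size=(5, 2)))
        res = intragroup_distances(dm, np.array(["a", "a", "a", "b", "b"]))
        assert len(res.distances["a"]) == 3
        assert len(res.distances["b"]) == 1

    def test_identical_groups_high_kw_p(self, rng):
        pts = rng.normal(size=(6, 2))
        dm = euclidean_dm(np.vstack([pts, pts]))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = intragroup_distances(dm, labels)
        assert res.kw_p_value > 0.5

    def test_dispersed_group_has_larger_median(self, rng):
        tight = rng.normal(scale=0.1, size=(8, 2))
        loose = rng.normal(scale=5.0, size=(8, 2))
        dm = euclidean_dm(np.vstack([tight, loose]))
        labels = np.array(["tight"] * 8 + ["loose"] * 8)
        res = intragroup_distances(dm, labels)
        assert (np.median(res.distances["loose"])
                > np.median(res.distances["tight"]))
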