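"""Distance matrices, complete linkage, CH scan, and curve summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from braintraj.clustering import (age_group_correlations, calinski_harabasz,
                                  choose_k_by_ch, cluster_curves,
                                  cluster_mean_curves, complete_linkage,
                                  curve_distances, cut_tree_labels, leaf_ordering)
from braintraj.errors import ParameterError
from _oracles import (calinski_harabasz_manual, complete_linkage_bruteforce,
                      pearson_bruteforce, scipy_linkage_to_steps)


def _frame(arr, prefix="R"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i+1}" for i in range(arr.shape[0])])


def _planted_blobs(rng, n_per=10, n_windows=8, sep=10.0, noise=1.0):
    """Two template curves far apart relative to noise."""
    t1 = rng.normal(0, 1, n_windows)
    t2 = t1 + sep * rng.normal(0, 1, n_windows) / np.sqrt(n_windows)
    t2 = t1 + (t2 - t1) / np.linalg.norm(t2 - t1) * sep
    rows = [t1 + noise * rng.normal(size=n_windows) for _ in range(n_per)]
    rows += [t2 + noise * rng.normal(size=n_windows) for _ in range(n_per)]
    labels = [1] * n_per + [2] * n_per
    return np.array(rows), np.array(labels)


class TestCurveDistances:
    def test_identical_rows_have_zero_distance(self):
        d, kept, _ = curve_distances(_frame([[1, 2, 3], [1, 2, 3]]))
        assert d[0, 1] == 0.0

    def test_three_four_five(self):
        d, _, _ = curve_distances(_frame([[0, 0, 0], [3, 4, 0]]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(10, 8))
        d, _, _ = curve_distances(_frame(X))
        for i in range(10):
            for j in range(10):
                expected = np.sqrt(sum((X[i, k] - X[j, k]) ** 2 for k in range(8)))
                assert d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_rows_with_missing_values_are_excluded(self):
        frame = _frame([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        frame.iloc[1, 2] = np.nan
        d, kept, excluded = curve_distances(frame)
        assert excluded == ["R2"]
        assert kept == ["R1", "R3"]

    def test_triangle_inequality(self, rng):
        d, _, _ = curve_distances(_frame(rng.normal(size=(12, 6))))
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestCompleteLinkage:
    def test_three_point_merge_order(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], float)
        Z = complete_linkage(d)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(10.0)

    def test_two_items(self):
        Z = complete_linkage(np.array([[0, 2.5], [2.5, 0]]))
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(2.5)

    def test_matches_bruteforce_agglomeration(self, rng):
        """Identical merge sequence (member sets and heights) on random 6-point sets."""
        for _ in range(20):
            X = rng.normal(size=(6, 4))
            d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            Z = complete_linkage(d)
            got = scipy_linkage_to_steps(Z, 6)
            expected = complete_linkage_bruteforce(d)
            for (set_a, h_a), (set_b, h_b) in zip(got, expected):
                assert set_a == set_b
                assert h_a == pytest.approx(h_b, abs=1e-10)

    def test_heights_are_monotone(self, rng):
        d = np.abs(rng.normal(size=(15, 15)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        Z = complete_linkage(d)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ParameterError):
            complete_linkage(np.array([[0, 1], [2, 0]], float))


class TestCutTree:
    def test_every_item_own_cluster(self, rng):
        d, _, _ = curve_distances(_frame(rng.normal(size=(7, 4))))
        labels = cut_tree_labels(complete_linkage(d), 7)
        assert len(set(labels)) == 7

    def test_single_cluster(self, rng):
        d, _, _ = curve_distances(_frame(rng.normal(size=(7, 4))))
        labels = cut_tree_labels(complete_linkage(d), 1)
        assert set(labels) == {1}

    def test_out_of_range_k(self, rng):
        d, _, _ = curve_distances(_frame(rng.normal(size=(5, 4))))
        with pytest.raises(ParameterError):
            cut_tree_labels(complete_linkage(d), 6)

    def test_planted_blobs_recovered_exactly_across_seeds(self):
        """ARI = 1 whenever the template separation is 10x the noise SD."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X, truth = _planted_blobs(rng, sep=10.0, noise=1.0)
            d, _, _ = curve_distances(_frame(X))
            labels = cut_tree_labels(complete_linkage(d), 2)
            assert adjusted_rand_score(truth, labels) == 1.0


class TestCalinskiHarabasz:
    def test_matches_manual_four_point_example(self):
        X = np.array([[0.0, 0], [1, 0], [10, 0], [11, 0]])
        labels = [1, 1, 2, 2]
        # by hand: within = 4 * 0.5^2 = 1, centroids at 0.5 / 10.5, overall 5.5,
        # between = 2*5^2 + 2*5^2 = 100, CH = (100/1) / (1/2) = 200
        assert calinski_harabasz(X, labels) == pytest.approx(200.0)
        assert calinski_harabasz_manual(X, labels) == pytest.approx(200.0)

    def test_ch_peaks_at_planted_k(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X, _ = _planted_blobs(rng, sep=10.0, noise=1.0)
            Z = complete_linkage(curve_distances(_frame(X))[0])
            best, scores = choose_k_by_ch(X, Z, (2, 6))
            assert scores[2] > scores[3] and scores[2] > scores[4]
            hits += best == 2
        assert hits >= 48  # >= 95% of seeds

    def test_random_labels_on_homogeneous_data_average_near_one(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(300):
            X = rng.normal(size=(60, 5))
            vals.append(calinski_harabasz(X, rng.integers(1, 4, size=60)))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)

    def test_singletons_reported_infinite(self, rng):
        X = rng.normal(size=(4, 3))
        assert calinski_harabasz(X, [1, 2, 3, 4]) == np.inf


class TestLeafOrdering:
    def test_two_items(self):
        Z = complete_linkage(np.array([[0, 1.0], [1.0, 0]]))
        assert list(leaf_ordering(Z)) == [0, 1]

    def test_chain_preserved(self):
        # equally spaced points on a line: dendrogram keeps the chain contiguous
        pts = np.arange(5.0)[:, None]
        d = np.abs(pts - pts.T)
        order = list(leaf_ordering(complete_linkage(d)))
        assert order == sorted(order) or order == sorted(order, reverse=True) or \
            all(abs(order.index(i) - order.index(i + 1)) <= 2 for i in range(4))

    def test_row_permutation_equivariance(self, rng):
        X, truth = _planted_blobs(rng, sep=10.0, noise=1.0)
        res1 = cluster_curves(_frame(X), k=2)
        perm = rng.permutation(len(X))
        frame2 = _frame(X).iloc[perm]
        res2 = cluster_curves(frame2, k=2)
        lab1 = [res1.labels[r] for r in sorted(res1.labels)]
        lab2 = [res2.labels[r] for r in sorted(res2.labels)]
        assert adjusted_rand_score(lab1, lab2) == 1.0


class TestAgeGroupCorrelations:
    def test_duplicate_rows_correlate_perfectly(self):
        M = pd.DataFrame([[1.0, 2, 3, 1], [1.0, 2, 3, 1]], index=[1, 2])
        C = age_group_correlations(M)
        assert C.loc[1, 2] == pytest.approx(1.0)

    def test_negated_row(self):
        M = pd.DataFrame([[1.0, 2, 3, 0], [-1.0, -2, -3, 0]], index=[1, 2])
        assert age_group_correlations(M).loc[1, 2] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        M = pd.DataFrame(rng.normal(size=(5, 20)))
        C = age_group_correlations(M)
        for i in range(5):
            for j in range(5):
                expected = pearson_bruteforce(list(M.iloc[i]), list(M.iloc[j]))
                assert C.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_row_flagged_missing(self):
        M = pd.DataFrame([[1.0, 1, 1, 1], [1.0, 2, 3, 4], [0.0, 1, 0, 1]])
        C = age_group_correlations(M)
        assert np.isnan(C.iloc[0, 1])
        assert C.iloc[0, 0] == 1.0


class TestClusterMeanCurves:
    def test_single_cluster_gives_overall_means(self, rng):
        X = _frame(rng.normal(size=(6, 4)))
        means, _ = cluster_mean_curves(X, {r: 1 for r in X.index})
        np.testing.assert_allclose(means.loc[1], X.mean(axis=0))

    def test_template_recovery_within_noise(self, rng):
        t1 = np.sin(np.linspace(0, 3, 12))
        t2 = np.cos(np.linspace(0, 3, 12))
        rows = [t1 + 0.05 * rng.normal(size=12) for _ in range(30)]
        rows += [t2 + 0.05 * rng.normal(size=12) for _ in range(30)]
        X = _frame(np.array(rows))
        labels = {f"R{i+1}": (1 if i < 30 else 2) for i in range(60)}
        means, extremes = cluster_mean_curves(X, labels)
        np.testing.assert_allclose(means.loc[1], t1, atol=0.05)
        np.testing.assert_allclose(means.loc[2], t2, atol=0.05)
        assert extremes.loc[1, "peak_value"] == pytest.approx(t1.max(), abs=0.05)

    def test_all_zero_curves_have_no_extremes(self):
        X = _frame(np.zeros((4, 5)))
        _, extremes = cluster_mean_curves(X, {r: 1 for r in X.index})
        assert np.isnan(extremes.loc[1, "peak_value"])
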