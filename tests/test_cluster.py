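"""Clustering engine: oracle equivalence, selection behavior, relabeling."""

import itertools

import numpy as np
import pytest

import raasid
from conftest import three_blobs


def brute_force_silhouette(X, labels):
    """O(n^2) silhouette from the definition; singleton clusters score 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    widths = np.zeros(n)
    for i in range(n):
        same = labels == labels[i]
        if same.sum() == 1:
            widths[i] = 0.0
            continue
        a = D[i, same].sum() / (same.sum() - 1)
        b = min(
            D[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        widths[i] = (b - a) / max(a, b)
    return widths.mean(), widths


def best_partition_inertia(X, k):
    """Minimal within-cluster sum of squares over all label assignments."""
    n = X.shape[0]
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        assign = np.asarray(assign)
        if len(set(assign)) < k:
            continue
        inertia = sum(
            ((X[assign == j] - X[assign == j].mean(axis=0)) ** 2).sum()
            for j in range(k)
        )
        best = min(best, inertia)
    return best


class TestKMeans:
    def test_two_obvious_1d_clusters(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        sol = raasid.kmeans_fit(X, 2, seed=0)
        # enumerate all 2-partitions: optimum splits {0,1} vs {10,11}
        assert sol.inertia == pytest.approx(best_partition_inertia(X, 2))
        assert sol.labels[0] == sol.labels[1] != sol.labels[2] == sol.labels[3]
        centers = sorted(sol.centroids[:, 0])
        assert centers == pytest.approx([0.5, 10.5])

    def test_k_equals_n_zero_inertia(self):
        X = np.array([[0.0], [3.0], [7.0], [20.0]])
        sol = raasid.kmeans_fit(X, 4, seed=0)
        assert sol.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(sol.labels)) == 4

    def test_duplication_invariance(self):
        X, _ = three_blobs(n_per=15, seed=2)
        sol1 = raasid.kmeans_fit(X, 3, seed=5)
        sol2 = raasid.kmeans_fit(np.vstack([X, X]), 3, seed=5)
        c1 = np.sort(sol1.centroids, axis=0)
        c2 = np.sort(sol2.centroids, axis=0)
        np.testing.assert_allclose(c1, c2, atol=1e-8)

    def test_attains_enumerated_optimum_on_small_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            X = rng.normal(size=(8, 2))
            sol = raasid.kmeans_fit(X, 2, restarts=25, seed=1)
            assert sol.inertia <= best_partition_inertia(X, 2) + 1e-8

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            raasid.kmeans_fit(np.zeros((2, 3)), 5)


class TestHierarchical:
    def test_matches_kmeans_on_separated_pairs(self):
        X = np.array([[0.0], [0.5], [10.0], [10.5]])
        h = raasid.hierarchical_fit(X, 2)
        km = raasid.kmeans_fit(X, 2, seed=0)
        # same partition (up to label permutation)
        assert (h.labels[0] == h.labels[1]) and (h.labels[2] == h.labels[3])
        assert h.inertia == pytest.approx(km.inertia)

    def test_k_one_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            raasid.hierarchical_fit(np.random.default_rng(0).normal(size=(5, 2)), 1)

    def test_n_equals_k_singletons(self):
        X = np.arange(8.0).reshape(4, 2)
        sol = raasid.hierarchical_fit(X, 4)
        assert len(set(sol.labels)) == 4
        assert sol.inertia == pytest.approx(0.0, abs=1e-12)


class TestFuzzyCMeans:
    def test_memberships_row_stochastic(self):
        X, _ = three_blobs(n_per=20, seed=4)
        sol = raasid.fuzzy_cmeans_fit(X, 3, seed=4)
        np.testing.assert_allclose(sol.memberships.sum(axis=1), 1.0, atol=1e-8)
        assert sol.converged

    def test_distant_tight_groups_near_crisp(self):
        rng = np.random.default_rng(5)
        X = np.vstack(
            [rng.normal(0, 0.01, (20, 2)), rng.normal(50, 0.01, (20, 2))]
        )
        sol = raasid.fuzzy_cmeans_fit(X, 2, m=2.0, seed=5)
        assert sol.memberships.max(axis=1).min() > 0.99

    def test_equidistant_point_half_membership(self):
        # two tight clusters and one point exactly between them
        X = np.array(
            [[-10.0, 0], [-10.0, 0.001], [10.0, 0], [10.0, 0.001], [0.0, 0.0005]]
        )
        sol = raasid.fuzzy_cmeans_fit(X, 2, m=2.0, seed=0)
        np.testing.assert_allclose(sol.memberships[-1], [0.5, 0.5], atol=1e-3)

    def test_fuzzifier_must_exceed_one(self):
        with pytest.raises(ValueError, match="m must exceed"):
            raasid.fuzzy_cmeans_fit(np.zeros((5, 2)), 2, m=1.0)


class TestSilhouette:
    def test_hand_computed_two_pair_instance(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([1, 1, 2, 2])
        mean, _ = raasid.silhouette_mean(X, labels)
        # a = 0.1 for every point; b = 10.05 for the outer points and 9.95
        # for the inner ones, so the mean width is ~0.990
        expected = ((10.05 - 0.1) / 10.05 + (9.95 - 0.1) / 9.95) / 2
        assert mean == pytest.approx(expected, abs=1e-10)
        assert mean == pytest.approx(0.990, abs=1e-3)

    def test_misassigned_points_nonpositive(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        labels = np.array([1, 2, 1, 2])  # perfectly mixed split
        _, widths = raasid.silhouette_mean(X, labels)
        assert (widths <= 0).all()

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            raasid.silhouette_mean(np.zeros((4, 2)), np.ones(4))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 40)
        k = rng.integers(2, 5)
        X = rng.normal(size=(n, 3))
        labels = rng.integers(1, k + 1, size=n)
        if len(np.unique(labels)) < 2:
            labels[0] = 1
            labels[1] = 2
        mean, widths = raasid.silhouette_mean(X, labels)
        bf_mean, bf_widths = brute_force_silhouette(X, labels)
        np.testing.assert_allclose(widths, bf_widths, atol=1e-10)
        assert mean == pytest.approx(bf_mean, abs=1e-10)


class TestSelection:
    def test_three_blobs_select_k3(self):
        X, _ = three_blobs(n_per=50, seed=6)
        report = raasid.select_clustering(X, seed=6)
        assert report.best_k == 3
        assert report.best_method == "kmeans"
        # exhaustive check: reported best equals grid argmax
        valid = report.grid.dropna(subset=["silhouette"])
        assert report.best_solution.silhouette == pytest.approx(
            valid["silhouette"].max()
        )

    def test_two_blobs_select_k2(self):
        rng = np.random.default_rng(7)
        X = np.vstack(
            [rng.normal(0, 0.3, (50, 3)), rng.normal(4, 0.3, (50, 3))]
        )
        report = raasid.select_clustering(X, seed=7)
        assert report.best_k == 2

    def test_wider_k_range_same_optimum(self):
        X, _ = three_blobs(n_per=50, seed=8)
        narrow = raasid.select_clustering(X, k_range=range(2, 7), seed=8)
        wide = raasid.select_clustering(X, k_range=range(2, 9), seed=8)
        assert (narrow.best_method, narrow.best_k) == (
            wide.best_method,
            wide.best_k,
        )

    def test_grid_shape(self):
        X, _ = three_blobs(n_per=20, seed=9)
        report = raasid.select_clustering(X, k_range=range(2, 9), seed=9)
        assert len(report.grid) == 21  # 3 methods x 7 candidate k


class TestPCA:
    def test_fractions_sum_to_one_descending(self, standardized_panel):
        std, _ = standardized_panel
        pca = raasid.pca_decompose(std.values)
        assert pca.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(pca.variance_fractions) <= 1e-12).all()
        # loadings orthonormal
        np.testing.assert_allclose(
            pca.loadings @ pca.loadings.T, np.eye(3), atol=1e-8
        )

    def test_spherical_data_equal_fractions(self):
        rng = np.random.default_rng(10)
        pca = raasid.pca_decompose(rng.standard_normal((5000, 3)))
        np.testing.assert_allclose(pca.variance_fractions, 1 / 3, atol=0.03)

    def test_collinear_data_single_component(self):
        t = np.linspace(0, 1, 50)
        X = np.column_stack([t, 2 * t, -t])
        pca = raasid.pca_decompose(X)
        np.testing.assert_allclose(
            pca.variance_fractions, [1.0, 0.0, 0.0], atol=1e-10
        )


class TestCanonicalRelabel:
    def test_orders_by_ascending_mean_log_ang1(
        self, canonical_solution, standardized_panel
    ):
        _, logm = standardized_panel
        means = [
            logm.values[canonical_solution.labels == j, 0].mean()
            for j in (1, 2, 3)
        ]
        assert means[0] < means[1] < means[2]

    def test_top_cluster_is_acei_like_for_pure_profiles(self):
        # with covariate effects silenced the three latent profiles are well
        # separated and the ascending-ang1 ordering puts the ACEi signature
        # (highest ang I, lowest ang II) in the top cluster
        cfg = raasid.default_config(seed=13)
        cfg.covariate_effects = {
            k: (0.0, 0.0, 0.0) for k in cfg.covariate_effects
        }
        cohort = raasid.generate_cohort(cfg)
        logm = np.log(cohort[list(raasid.BIOMARKERS)].to_numpy())
        std = (logm - logm.mean(0)) / logm.std(0)
        sol = raasid.canonical_relabel(
            raasid.kmeans_fit(std, 3, seed=13), logm
        )
        ang1 = [logm[sol.labels == j, 0].mean() for j in (1, 2, 3)]
        ang2 = [logm[sol.labels == j, 1].mean() for j in (1, 2, 3)]
        assert ang1[2] == max(ang1)
        assert ang2[2] == min(ang2)

    def test_signature_identification(self, canonical_solution, standardized_panel):
        _, logm = standardized_panel
        roles = raasid.identify_drug_clusters(
            canonical_solution.labels, logm.values
        )
        assert set(roles) == {"non_raas", "acei", "arb"}
        assert len(set(roles.values())) == 3
        ang2 = {
            c: logm.values[canonical_solution.labels == c, 1].mean()
            for c in (1, 2, 3)
        }
        assert ang2[roles["acei"]] == min(ang2.values())
        assert ang2[roles["arb"]] == max(ang2.values())

    def test_invariant_to_label_permutation_and_idempotent(
        self, standardized_panel
    ):
        std, logm = standardized_panel
        sol = raasid.kmeans_fit(std.values, 3, seed=1)
        canon = raasid.canonical_relabel(sol, logm.values)
        # permute incoming labels and relabel again
        perm = {1: 3, 2: 1, 3: 2}
        permuted = raasid.ClusterSolution(
            method=sol.method,
            k=sol.k,
            labels=np.array([perm[l] for l in sol.labels]),
            centroids=sol.centroids[[1, 2, 0]],
            inertia=sol.inertia,
        )
        canon2 = raasid.canonical_relabel(permuted, logm.values)
        np.testing.assert_array_equal(canon.labels, canon2.labels)
        again = raasid.canonical_relabel(canon, logm.values)
        np.testing.assert_array_equal(canon.labels, again.labels)
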