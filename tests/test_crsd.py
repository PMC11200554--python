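"""The cross-entropy referenced pseudometric and clustering on posteriors."""

import numpy as np
import pytest
from scipy import stats

from cytovae.crsd import (
    ReferenceSet,
    agglomerative_crsd,
    baseline_cluster,
    clustering_metrics,
    cross_entropy_gaussian,
    crsd_matrix,
    crsd_multi,
    crsd_single,
)
from cytovae.scoring import GaussianDensity
from cytovae.synthetic import LatentPosterior, generate_latent_fixture


def _random_gaussian(rng, dim, diagonal=False):
    mean = rng.normal(size=dim)
    if diagonal:
        return LatentPosterior(mean, rng.uniform(0.3, 2.0, dim))
    a = rng.normal(size=(dim, dim))
    return GaussianDensity(mean, a @ a.T + 0.5 * np.eye(dim))


class TestCrossEntropy:
    def test_self_cross_entropy_is_entropy(self):
        r = GaussianDensity(np.zeros(1), np.eye(1))
        assert cross_entropy_gaussian(r, r) == pytest.approx(0.5 * np.log(2 * np.pi * np.e))

    def test_hand_value_and_monte_carlo(self):
        r = GaussianDensity(np.zeros(1), np.eye(1))
        q = GaussianDensity(np.array([2.0]), np.eye(1))
        closed = cross_entropy_gaussian(r, q)
        assert closed == pytest.approx(0.5 * np.log(2 * np.pi) + 2.5)
        rng = np.random.default_rng(0)
        x = rng.normal(size=1_000_000)
        vals = -stats.norm(2.0, 1.0).logpdf(x)
        assert closed == pytest.approx(vals.mean(), abs=3 * vals.std() / 1000)

    def test_monte_carlo_oracle_random_pairs(self):
        """Closed form vs Monte-Carlo -E_r[log q] on random full/diagonal
        Gaussian pairs in up to 4 dimensions."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            dim = int(rng.integers(1, 5))
            r = _random_gaussian(rng, dim, diagonal=bool(rng.integers(2)))
            q = _random_gaussian(rng, dim, diagonal=bool(rng.integers(2)))
            closed = cross_entropy_gaussian(r, q)
            cov_r = np.diag(r.stddev**2) if isinstance(r, LatentPosterior) else r.covariance
            cov_q = np.diag(q.stddev**2) if isinstance(q, LatentPosterior) else q.covariance
            x = rng.multivariate_normal(r.mean, cov_r, size=1_000_000)
            vals = -stats.multivariate_normal(q.mean, cov_q).logpdf(x)
            se = vals.std() / np.sqrt(len(vals))
            assert closed == pytest.approx(vals.mean(), abs=3 * se)

    def test_gibbs_inequality(self):
        """CE(r, q) >= H(r), equality iff q = r."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            dim = int(rng.integers(1, 6))
            r = _random_gaussian(rng, dim)
            q = _random_gaussian(rng, dim)
            h_r = cross_entropy_gaussian(r, r)
            assert cross_entropy_gaussian(r, q) >= h_r - 1e-10
        r = _random_gaussian(rng, 3)
        assert cross_entropy_gaussian(r, r) == pytest.approx(
            cross_entropy_gaussian(r, GaussianDensity(r.mean.copy(), r.covariance.copy()))
        )

    def test_singular_q_rejected(self):
        r = GaussianDensity(np.zeros(2), np.eye(2))
        q = GaussianDensity(np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="positive definite"):
            cross_entropy_gaussian(r, q)


class TestCrsd:
    def test_zero_for_identical_densities(self):
        rng = np.random.default_rng(3)
        r = _random_gaussian(rng, 4)
        p = _random_gaussian(rng, 4)
        assert crsd_single(p, p, r) == 0.0

    def test_zero_for_mirrored_means(self):
        """Unit-covariance Gaussians at +mu and -mu are indistinguishable
        through a reference centered at the origin, although p != q."""
        for dim in (1, 8):
            mu = np.ones(dim)
            p = GaussianDensity(mu, np.eye(dim))
            q = GaussianDensity(-mu, np.eye(dim))
            r = GaussianDensity(np.zeros(dim), np.eye(dim))
            assert crsd_single(p, q, r) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_one_dimension(self):
        r = GaussianDensity(np.zeros(1), np.eye(1))
        p = GaussianDensity(np.array([1.0]), np.eye(1))
        q = GaussianDensity(np.array([2.0]), np.eye(1))
        # |(0.5 log 2pi + 1) - (0.5 log 2pi + 2.5)| = 1.5
        assert crsd_single(p, q, r) == pytest.approx(1.5)

    def test_duplicate_reference_additivity(self):
        rng = np.random.default_rng(4)
        p, q, r = (_random_gaussian(rng, 3) for _ in range(3))
        single = crsd_single(p, q, r)
        assert crsd_multi(p, q, ReferenceSet.of(r, r)) == pytest.approx(2 * single)

    def test_multi_zero_for_identical(self):
        rng = np.random.default_rng(5)
        p = _random_gaussian(rng, 2)
        refs = ReferenceSet.of(*(_random_gaussian(rng, 2) for _ in range(4)))
        assert crsd_multi(p, p, refs) == 0.0

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ReferenceSet(densities=())

    @pytest.mark.parametrize("dim", [1, 8])
    def test_pseudometric_axioms(self, dim):
        """Symmetry, non-negativity and the triangle inequality on random
        Gaussian triples, for single and multi-reference CRSD."""
        rng = np.random.default_rng(100 + dim)
        refs = ReferenceSet.of(
            *(_random_gaussian(rng, dim, diagonal=bool(rng.integers(2))) for _ in range(3))
        )
        for _ in range(250):
            p, q, s = (
                _random_gaussian(rng, dim, diagonal=bool(rng.integers(2)))
                for _ in range(3)
            )
            r = refs.densities[0]
            d_pq = crsd_single(p, q, r)
            assert d_pq >= 0.0
            assert d_pq == pytest.approx(crsd_single(q, p, r), abs=1e-9)
            assert d_pq <= crsd_single(p, s, r) + crsd_single(s, q, r) + 1e-9
            m_pq = crsd_multi(p, q, refs)
            assert m_pq >= 0.0
            assert m_pq == pytest.approx(crsd_multi(q, p, refs), abs=1e-9)
            assert m_pq <= crsd_multi(p, s, refs) + crsd_multi(s, q, refs) + 1e-9


class TestCrsdMatrix:
    def test_single_posterior(self):
        p = LatentPosterior(np.zeros(2), np.ones(2))
        m = crsd_matrix([p], ReferenceSet.of(p))
        np.testing.assert_array_equal(m, [[0.0]])

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(6)
        posts = [_random_gaussian(rng, 3, diagonal=True) for _ in range(10)]
        refs = ReferenceSet.from_posteriors(posts)
        m = crsd_matrix(posts, refs)
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 0.0)

    def test_shared_covariance_closed_form(self):
        """With identical covariances and R = {standard normal}, the entry is
        half the absolute difference of squared mean norms."""
        rng = np.random.default_rng(7)
        sd = np.full(3, 0.8)
        posts = [LatentPosterior(rng.normal(size=3), sd.copy()) for _ in range(6)]
        refs = ReferenceSet.of(GaussianDensity(np.zeros(3), np.eye(3)))
        m = crsd_matrix(posts, refs)
        # CE(r, p_i) = 0.5 [sum log 2 pi sd^2 + sum (1 + mu_i^2)/sd^2]; the
        # shared terms cancel in the difference
        for i in range(6):
            for j in range(6):
                expected = 0.5 * abs(
                    np.sum(posts[i].mean**2) - np.sum(posts[j].mean**2)
                ) / sd[0] ** 2
                assert m[i, j] == pytest.approx(expected, abs=1e-10)


class TestAgglomerativeCrsd:
    def test_planted_partition_recovered_exactly(self):
        rng = np.random.default_rng(8)
        within = rng.uniform(0.5, 1.0, size=(20, 20))
        m = np.zeros((20, 20))
        m[:10, :10] = within[:10, :10]
        m[10:, 10:] = within[10:, 10:]
        m[:10, 10:] = 1000.0 + rng.uniform(size=(10, 10))
        m = np.triu(m, 1)
        m = m + m.T
        m[10:, :10] = m[:10, 10:].T
        result = agglomerative_crsd(m, n_clusters=2)
        truth = np.repeat([0, 1], 10)
        h, c, v = clustering_metrics(truth, result.labels)
        assert h == c == v == 1.0

    def test_each_point_its_own_cluster(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 2, size=(5, 5))
        m = np.triu(x, 1)
        m = m + m.T
        result = agglomerative_crsd(m, n_clusters=5)
        assert sorted(result.labels) == [0, 1, 2, 3, 4]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        posts = [_random_gaussian(rng, 2, diagonal=True) for _ in range(12)]
        refs = ReferenceSet.from_posteriors(posts)
        m = crsd_matrix(posts, refs)
        perm = rng.permutation(12)
        r1 = agglomerative_crsd(m, n_clusters=3).labels
        r2 = agglomerative_crsd(m[np.ix_(perm, perm)], n_clusters=3).labels
        # same partition up to label renaming
        h, c, v = clustering_metrics(r1[perm], r2)
        assert v == pytest.approx(1.0)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError, match="n_clusters"):
            agglomerative_crsd(np.zeros((3, 3)), n_clusters=4)


class TestBaselines:
    def test_kmeans_separates_two_blobs(self):
        rng = np.random.default_rng(11)
        x = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(10, 0.1, (20, 2))])
        res = baseline_cluster(x, "kmeans", n_clusters=2, seed=0)
        truth = np.repeat([0, 1], 20)
        assert clustering_metrics(truth, res.labels)[2] == 1.0

    def test_dbscan_identical_points_single_cluster(self):
        x = np.zeros((10, 3))
        res = baseline_cluster(x, "dbscan")
        assert res.n_clusters == 1

    def test_agglomerative_two_path_equivalence(self):
        """Feature-space average-linkage clustering equals average linkage on
        the precomputed Euclidean distance matrix."""
        rng = np.random.default_rng(12)
        x = rng.normal(size=(30, 4))
        res_feat = baseline_cluster(
            x, "agglomerative-euclidean", n_clusters=5, params={"linkage": "average"}
        )
        from scipy.spatial.distance import cdist

        res_mat = agglomerative_crsd(cdist(x, x), n_clusters=5, linkage="average")
        h, c, v = clustering_metrics(res_feat.labels, res_mat.labels)
        assert v == pytest.approx(1.0)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            baseline_cluster(np.zeros((4, 2)), "meanshift")


def _entropy_metrics_bruteforce(labels_true, labels_pred):
    """Direct evaluation of the entropy formulas for h, c and V."""
    labels_true, labels_pred = np.asarray(labels_true), np.asarray(labels_pred)
    n = len(labels_true)

    def entropy(labels):
        _, counts = np.unique(labels, return_counts=True)
        p = counts / n
        return -np.sum(p * np.log(p))

    def cond_entropy(a, b):
        # H(a | b)
        total = 0.0
        for vb in np.unique(b):
            mask = b == vb
            pb = mask.sum() / n
            _, counts = np.unique(a[mask], return_counts=True)
            pc = counts / mask.sum()
            total += pb * -np.sum(pc * np.log(pc))
        return total

    h_c, h_k = entropy(labels_true), entropy(labels_pred)
    h = 1.0 if h_c == 0 else 1.0 - cond_entropy(labels_true, labels_pred) / h_c
    c = 1.0 if h_k == 0 else 1.0 - cond_entropy(labels_pred, labels_true) / h_k
    v = 0.0 if h + c == 0 else 2 * h * c / (h + c)
    return h, c, v


class TestClusteringMetrics:
    def test_relabeling_is_perfect(self):
        truth = [0, 0, 1, 1, 2, 2]
        pred = [5, 5, 3, 3, 9, 9]
        assert clustering_metrics(truth, pred) == (1.0, 1.0, 1.0)

    def test_single_cluster_limits(self):
        truth = [0, 0, 1, 1]
        pred = [0, 0, 0, 0]
        h, c, v = clustering_metrics(truth, pred)
        assert h == 0.0 and c == 1.0

    def test_matches_bruteforce_entropy_formulas(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            truth = rng.integers(0, 3, size=60)
            pred = rng.integers(0, 5, size=60)
            expected = _entropy_metrics_bruteforce(truth, pred)
            got = clustering_metrics(truth, pred)
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            clustering_metrics([], [])


class TestUncertaintyInformedClustering:
    def test_crsd_beats_euclidean_when_stddev_carries_signal(self):
        """Two groups share the same mean location but differ in posterior
        spread: CRSD clustering (Agg-SM) sees the spread, mean-based
        agglomerative clustering (Agg-EM) cannot. Averaged over seeds,
        Agg-SM's homogeneity and V-measure are at least Agg-EM's."""
        v_sm, v_em, h_sm, h_em = [], [], [], []
        for seed in range(10):
            posts, truth = generate_latent_fixture(
                n=60, dim=8,
                component_means=[np.zeros(8), np.zeros(8)],
                component_stddevs=[np.full(8, 0.3), np.full(8, 1.5)],
                assignment=np.repeat([0, 1], 30), seed=seed,
            )
            refs = ReferenceSet.from_posteriors(posts)
            m = crsd_matrix(posts, refs)
            sm = agglomerative_crsd(m, n_clusters=2)
            means = np.array([p.mean for p in posts])
            em = baseline_cluster(means, "agglomerative-euclidean", n_clusters=2)
            h1, _, v1 = clustering_metrics(truth, sm.labels)
            h2, _, v2 = clustering_metrics(truth, em.labels)
            h_sm.append(h1), h_em.append(h2), v_sm.append(v1), v_em.append(v2)
        assert np.mean(v_sm) >= np.mean(v_em)
        assert np.mean(h_sm) >= np.mean(h_em)
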