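"""Cross-entropy-based referenced statistical distance (CRSD) and clustering.

Latent posteriors are distributions, not points. To cluster them without
collapsing each to its mean, we compare two densities p and q through a
reference density r by the absolute difference of cross-entropies,

    d(p, q; r) = | CE(r, q) - CE(r, p) |,      CE(r, q) = -∫ r(x) log q(x) dx,

and, for a finite reference set R, d(p, q; R) = sum_{r in R} d(p, q; r).
This is a pseudometric: symmetric, non-negative, zero at p = q (but also at
distinct p, q equidistant in cross-entropy from r, e.g. unit-covariance
Gaussians at +mu and -mu with r centered), and satisfies the triangle
inequality. For Gaussians the cross-entropy is closed-form:

    CE(r, q) = 0.5 [ log det(2 pi S_q) + tr(S_q^{-1} S_r)
                     + (m_r - m_q)^T S_q^{-1} (m_r - m_q) ].

Agglomerative clustering runs directly on the precomputed CRSD matrix
(average linkage — centroid-style linkages need coordinates, which a
pseudometric does not supply). Baseline clusterers operate on posterior
means as fixed points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.metrics import homogeneity_completeness_v_measure

from .scoring import GaussianDensity
from .synthetic import LatentPosterior

__all__ = [
    "ReferenceSet",
    "ClusterResult",
    "cross_entropy_gaussian",
    "crsd_single",
    "crsd_multi",
    "crsd_matrix",
    "agglomerative_crsd",
    "baseline_cluster",
    "clustering_metrics",
]

Density = GaussianDensity | LatentPosterior

_LOG2PI = np.log(2.0 * np.pi)


def _mean_cov(p: Density) -> tuple[np.ndarray, np.ndarray | None]:
    """Return (mean, cov) with cov=None marking a diagonal (stddev) density."""
    if isinstance(p, LatentPosterior):
        return p.mean, None
    return p.mean, p.covariance


def _as_diag_var(p: Density) -> np.ndarray | None:
    if isinstance(p, LatentPosterior):
        return p.stddev**2
    return None


@dataclass(frozen=True)
class ReferenceSet:
    """A finite, non-empty set of reference densities."""

    densities: tuple

    def __post_init__(self):
        if len(self.densities) == 0:
            raise ValueError("reference set must be non-empty")

    def __len__(self):
        return len(self.densities)

    def __iter__(self):
        return iter(self.densities)

    @classmethod
    def of(cls, *densities: Density) -> "ReferenceSet":
        return cls(densities=tuple(densities))

    @classmethod
    def from_posteriors(cls, posteriors, max_size: int | None = None,
                        seed: int = 0) -> "ReferenceSet":
        """Use fold posteriors as references, optionally subsampled (seeded)."""
        posteriors = list(posteriors)
        if max_size is not None and len(posteriors) > max_size:
            idx = np.random.default_rng(seed).choice(
                len(posteriors), size=max_size, replace=False
            )
            posteriors = [posteriors[i] for i in sorted(idx)]
        return cls(densities=tuple(posteriors))


def cross_entropy_gaussian(r: Density, q: Density) -> float:
    """Closed-form Gaussian cross-entropy CE(r, q) = -E_r[log q], in nats."""
    mr, cr = _mean_cov(r)
    mq, cq = _mean_cov(q)
    if mr.shape != mq.shape:
        raise ValueError("dimension mismatch between r and q")
    vr = _as_diag_var(r)
    vq = _as_diag_var(q)
    if vq is not None and (vr is not None):
        # both diagonal: elementwise closed form
        diff = mr - mq
        return float(0.5 * np.sum(np.log(2.0 * np.pi * vq) + (vr + diff**2) / vq))
    d = mr.shape[0]
    cr_full = np.diag(vr) if vr is not None else cr
    cq_full = np.diag(vq) if vq is not None else cq
    sign, logdet = np.linalg.slogdet(cq_full)
    if sign <= 0:
        raise ValueError("q covariance must be positive definite")
    sol = np.linalg.solve(cq_full, cr_full)
    diff = mr - mq
    maha = diff @ np.linalg.solve(cq_full, diff)
    return float(0.5 * (d * _LOG2PI + logdet + np.trace(sol) + maha))


def crsd_single(p: Density, q: Density, r: Density) -> float:
    """|CE(r, q) - CE(r, p)|: symmetric in (p, q), zero at p = q."""
    return abs(cross_entropy_gaussian(r, q) - cross_entropy_gaussian(r, p))


def crsd_multi(p: Density, q: Density, refs: ReferenceSet) -> float:
    """Sum of single-reference CRSDs over the reference set."""
    return float(sum(crsd_single(p, q, r) for r in refs))


def crsd_matrix(posteriors, refs: ReferenceSet) -> np.ndarray:
    """Pairwise CRSD matrix: symmetric, zero diagonal.

    Entry (i, j) = sum_r |CE(r, p_i) - CE(r, p_j)|, computed from the
    |R| x n table of cross-entropies (each pairwise term reuses the same
    CE(r, p_i) values, so the cost is O(|R| n) CE evaluations + O(|R| n^2)
    subtractions).
    """
    posteriors = list(posteriors)
    n = len(posteriors)
    ce = np.empty((len(refs), n))
    for a, r in enumerate(refs):
        for i, p in enumerate(posteriors):
            ce[a, i] = cross_entropy_gaussian(r, p)
    mat = np.abs(ce[:, :, None] - ce[:, None, :]).sum(axis=0)
    np.fill_diagonal(mat, 0.0)
    return mat


@dataclass
class ClusterResult:
    """Labels plus the dissimilarity matrix and quality scores, if computed."""

    labels: np.ndarray
    n_clusters: int
    linkage: str | None = None
    dissimilarity: np.ndarray | None = None
    homogeneity: float | None = None
    completeness: float | None = None
    v_measure: float | None = None

    def with_metrics(self, labels_true) -> "ClusterResult":
        h, c, v = clustering_metrics(labels_true, self.labels)
        self.homogeneity, self.completeness, self.v_measure = h, c, v
        return self


def agglomerative_crsd(
    matrix: np.ndarray, n_clusters: int = 100, linkage: str = "average"
) -> ClusterResult:
    """Hierarchical clustering on a precomputed CRSD matrix.

    Merges under the chosen linkage (default average); ties are broken by
    scipy's deterministic ordering of the condensed matrix. n_clusters = n
    returns the discrete partition.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds n={n}")
    if n == 1:
        return ClusterResult(labels=np.zeros(1, int), n_clusters=1,
                             linkage=linkage, dissimilarity=matrix)
    z = hierarchy.linkage(squareform(matrix, checks=False), method=linkage)
    raw = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    # relabel to 0..k-1 in order of first appearance
    _, labels = np.unique(raw, return_inverse=True)
    return ClusterResult(
        labels=labels, n_clusters=int(labels.max()) + 1,
        linkage=linkage, dissimilarity=matrix,
    )


_BASELINES = ("agglomerative-euclidean", "kmeans", "spectral", "dbscan")


def baseline_cluster(
    latent_means: np.ndarray,
    algorithm: str,
    n_clusters: int = 100,
    seed: int = 0,
    params: dict | None = None,
) -> ClusterResult:
    """Conventional clusterers on posterior means (fixed points).

    Library defaults are kept except where a parameter is required
    (n_clusters; DBSCAN eps=0.5, min_samples=5). `params` overrides
    keyword arguments of the underlying estimator.
    """
    x = np.asarray(latent_means, dtype=np.float64)
    params = dict(params or {})
    if algorithm == "agglomerative-euclidean":
        est = AgglomerativeClustering(n_clusters=n_clusters, **params)
    elif algorithm == "kmeans":
        est = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10, **params)
    elif algorithm == "spectral":
        est = SpectralClustering(n_clusters=n_clusters, random_state=seed, **params)
    elif algorithm == "dbscan":
        est = DBSCAN(**{"eps": 0.5, "min_samples": 5, **params})
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {_BASELINES}")
    raw = est.fit_predict(x)
    _, labels = np.unique(raw, return_inverse=True)
    return ClusterResult(labels=labels, n_clusters=int(labels.max()) + 1,
                         linkage=getattr(est, "linkage", None))


def clustering_metrics(labels_true, labels_pred) -> tuple[float, float, float]:
    """Homogeneity, completeness and their harmonic mean (V-measure)."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.size == 0:
        raise ValueError("empty label arrays")
    if labels_true.shape != labels_pred.shape:
        raise ValueError("label arrays must have equal length")
    h, c, v = homogeneity_completeness_v_measure(labels_true, labels_pred)
    return float(h), float(c), float(v)
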