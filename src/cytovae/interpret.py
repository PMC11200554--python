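"""Latent-space interpretation: traversals, pairwise densities, queries.

A traversal decodes images along an even grid in one latent dimension —
from -span to +span standard deviations about the center of the
(non-augmented) normal-data latent distribution, all other coordinates held
at the center — to read off that dimension's visual meaning. Pairwise
kernel-density summaries show where each diagnostic group lives in latent
space; cluster queries return the co-clustered neighbours of a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .crsd import ClusterResult
from .vae import TrainState, decode

__all__ = [
    "TraversalGrid",
    "latent_traversal",
    "pairwise_density_summary",
    "query_cluster",
    "cluster_composition",
]


@dataclass(frozen=True)
class TraversalGrid:
    """Decoded images along one latent dimension."""

    dim: int
    values: np.ndarray  # (steps,), strictly increasing, symmetric about center
    images: np.ndarray  # (steps, H, W, 3)


def latent_traversal(
    state: TrainState,
    center: np.ndarray,
    stddevs: np.ndarray,
    dim: int,
    steps: int = 10,
    span: float = 4.0,
) -> TraversalGrid:
    """Decode `steps` points from center - span*sd to center + span*sd.

    Endpoints are inclusive; the decoder's mean output is used (no sampling),
    so the grid is exactly reproducible from its arguments.
    """
    center = np.asarray(center, dtype=np.float64)
    stddevs = np.asarray(stddevs, dtype=np.float64)
    d = state.config.latent_dim
    if center.shape != (d,) or stddevs.shape != (d,):
        raise ValueError(f"center and stddevs must have shape ({d},)")
    if not (0 <= dim < d):
        raise ValueError(f"dim {dim} out of range for latent_dim {d}")
    values = center[dim] + np.linspace(-span, span, steps) * stddevs[dim]
    z = np.tile(center, (steps, 1))
    z[:, dim] = values
    return TraversalGrid(dim=dim, values=values, images=decode(z, state))


def pairwise_density_summary(
    latent_means: np.ndarray,
    class_labels,
    merge_map: dict[str, str] | None = None,
    grid_size: int = 100,
    span: float = 4.0,
) -> dict:
    """Per-group 2-D KDE grids for every latent dimension pair.

    Labels are first mapped through `merge_map` (e.g. pooling LSIL with
    ASC-US and HSIL with ASC-H, the usual display grouping); groups with
    fewer than 2 samples are skipped with a warning. Each grid uses Scott's
    bandwidth and covers mean +/- span standard deviations per dimension;
    densities are renormalized to integrate to 1 over the grid.

    Returns {"axes": {(i, j): (xi, yj)}, "groups": {g: {(i, j): grid}}}.
    """
    x = np.asarray(latent_means, dtype=np.float64)
    labels = [merge_map.get(l, l) if merge_map else l for l in class_labels]
    labels = np.asarray(labels)
    if x.shape[0] != labels.shape[0]:
        raise ValueError("latent_means and class_labels length mismatch")
    d = x.shape[1]
    mu, sd = x.mean(axis=0), x.std(axis=0)
    axes = {
        (i, j): (
            np.linspace(mu[i] - span * sd[i], mu[i] + span * sd[i], grid_size),
            np.linspace(mu[j] - span * sd[j], mu[j] + span * sd[j], grid_size),
        )
        for i in range(d)
        for j in range(i + 1, d)
    }
    out: dict[str, dict] = {}
    for g in np.unique(labels):
        xg = x[labels == g]
        if len(xg) < 2:
            warnings.warn(f"group {g!r} has fewer than 2 samples; skipped", stacklevel=2)
            continue
        grids = {}
        for (i, j), (xi, yj) in axes.items():
            kde = gaussian_kde(xg[:, [i, j]].T)  # Scott's rule
            gx, gy = np.meshgrid(xi, yj, indexing="ij")
            dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(grid_size, grid_size)
            cell = (xi[1] - xi[0]) * (yj[1] - yj[0])
            total = dens.sum() * cell
            grids[(i, j)] = dens / total if total > 0 else dens
        out[str(g)] = grids
    return {"axes": axes, "groups": out}


def query_cluster(
    sample_index: int,
    cluster_result: ClusterResult,
    annotations=None,
) -> list[dict]:
    """Co-cluster members of a sample, sorted by dissimilarity to it.

    Returns one record per member (query excluded) with its index,
    dissimilarity to the query, and — if `annotations` (a sequence aligned
    with the clustering, e.g. a DataFrame or list of labels) is given — the
    member's annotation.
    """
    labels = cluster_result.labels
    n = len(labels)
    if not (0 <= sample_index < n):
        raise IndexError(f"sample_index {sample_index} out of range [0, {n})")
    members = np.flatnonzero(labels == labels[sample_index])
    members = members[members != sample_index]
    if cluster_result.dissimilarity is not None:
        dists = cluster_result.dissimilarity[sample_index, members]
    else:
        dists = np.zeros(len(members))
    order = np.argsort(dists, kind="stable")
    out = []
    for m, dist in zip(members[order], dists[order]):
        rec = {"index": int(m), "dissimilarity": float(dist)}
        if annotations is not None:
            try:
                rec["annotation"] = annotations.iloc[int(m)].to_dict()  # DataFrame
            except AttributeError:
                rec["annotation"] = annotations[int(m)]
        out.append(rec)
    return out


def cluster_composition(cluster_result: ClusterResult, class_labels) -> list[dict]:
    """Per-cluster class counts, ranked by homogeneity (purity) then size."""
    labels = cluster_result.labels
    classes = np.asarray(class_labels)
    rows = []
    for c in range(cluster_result.n_clusters):
        members = classes[labels == c]
        values, counts = np.unique(members, return_counts=True)
        rows.append(
            {
                "cluster": int(c),
                "size": int(len(members)),
                "composition": {str(v): int(n) for v, n in zip(values, counts)},
                "purity": float(counts.max() / len(members)),
            }
        )
    rows.sort(key=lambda r: (-r["purity"], -r["size"]))
    return rows
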