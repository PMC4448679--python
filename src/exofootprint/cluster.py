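"""Occupancy selection and k-means clustering of per-site footprints.

Heterogeneous binding modes (for example a motif bound in either
orientation by an asymmetric protein) appear as distinct per-site
coverage shapes. Sites are ranked by total window 5' count, the top-n
are kept, and each site's concatenated (forward, reverse) coverage
vector is clustered with standard squared-Euclidean k-means. Scaling
each vector to unit total (the default) makes the clustering respond to
footprint *shape* rather than raw occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .coverage import FootprintProfile, ProfileMatrix, aggregate_footprint


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    centroids: np.ndarray  # (k, 2 * width), mean vector of each cluster's members
    inertia: float
    sizes: np.ndarray


def select_top_occupied(matrix: ProfileMatrix, n: int) -> ProfileMatrix:
    """The n sites with the largest total window count, occupancy-ordered.

    Ties break by genomic coordinate (chrom, start, strand).
    """
    if n > matrix.n_sites:
        raise ValueError(f"requested {n} sites but matrix has {matrix.n_sites}")
    totals = matrix.site_totals()
    order = sorted(
        range(matrix.n_sites),
        key=lambda i: (
            -totals[i],
            matrix.sites[i].site.chrom,
            matrix.sites[i].site.start,
            matrix.sites[i].site.strand,
        ),
    )
    return matrix.subset(order[:n])


def site_vectors(matrix: ProfileMatrix, scale: bool = True) -> np.ndarray:
    """Per-site feature vectors: forward window then reverse window.

    With ``scale``, each vector is divided by its own total count
    (all-zero sites are left as zeros).
    """
    X = np.concatenate([matrix.values[:, :, 0], matrix.values[:, :, 1]], axis=1)
    if scale:
        totals = X.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            X = np.where(totals > 0, X / totals, X)
    return X


def cluster_sites(
    matrix: ProfileMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    scale: bool = True,
) -> ClusterResult:
    """k-means on per-site coverage vectors; best of ``n_init`` restarts.

    Deterministic given ``seed``. Centroids and inertia are recomputed
    from the final assignment so that each centroid is exactly the mean
    of its members.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.n_sites:
        raise ValueError(f"k={k} exceeds the number of sites ({matrix.n_sites})")
    X = site_vectors(matrix, scale=scale)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed))
    labels = km.fit_predict(X)
    centroids = np.zeros((k, X.shape[1]))
    for c in range(k):
        members = X[labels == c]
        if members.size:
            centroids[c] = members.mean(axis=0)
    inertia = float(((X - centroids[labels]) ** 2).sum())
    return ClusterResult(
        k=k,
        labels=labels,
        centroids=centroids,
        inertia=inertia,
        sizes=np.bincount(labels, minlength=k),
    )


def cluster_profiles(matrix: ProfileMatrix, result: ClusterResult) -> list[FootprintProfile]:
    """Raw-count footprint profile of each cluster's member sites."""
    profiles = []
    for c in range(result.k):
        idx = np.nonzero(result.labels == c)[0]
        if idx.size == 0:
            zero = np.zeros(matrix.positions.size)
            profiles.append(FootprintProfile(matrix.positions.copy(), zero.copy(), zero.copy(), 0))
        else:
            profiles.append(aggregate_footprint(matrix.subset(idx)))
    return profiles
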