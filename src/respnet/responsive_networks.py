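"""Across-condition comparison of response eigenspaces: similarity, clustering,
alignment, and the repertoire of responsive networks.

Eigenspaces from different stimulation sites are compared with a rotation-
invariant subspace similarity (mean principal-angle cosine), clustered with
k-means on the similarity-matrix rows (cluster count chosen by the gap
statistic), and the members of each cluster are rotated onto a reference via
orthogonal Procrustes and averaged to give one spatial pattern set per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import InvalidArgumentError
from .response_decomposition import ResponseEigenspace, canonical_sign

__all__ = [
    "NetworkCluster",
    "eigenspace_similarity",
    "similarity_matrix",
    "cluster_eigenspaces",
    "align_and_average",
    "repertoire_counts",
]

log = logging.getLogger(__name__)

KMEANS_RESTARTS = 20
EFFECTIVE_SITE_THRESHOLD = 0.8


@dataclass
class NetworkCluster:
    """Aligned average of the eigenspaces assigned to one cluster."""

    member_conditions: list[dict]
    reference_member: int  # index into the member list
    mean_eigenvectors: np.ndarray  # (n_nodes, k), re-orthonormalized

    def validate(self) -> None:
        g = self.mean_eigenvectors.T @ self.mean_eigenvectors
        if not np.allclose(g, np.eye(g.shape[0]), atol=1e-8):
            raise InvalidArgumentError("cluster mean basis is not orthonormal")


def _basis(space: ResponseEigenspace | np.ndarray) -> np.ndarray:
    return space.eigenvectors if isinstance(space, ResponseEigenspace) else space


def eigenspace_similarity(
    a: ResponseEigenspace | np.ndarray, b: ResponseEigenspace | np.ndarray
) -> float:
    """Mean principal-angle cosine between two orthonormal bases, in [0, 1].

    Invariant to rotations within each subspace; reduces to the absolute dot
    product for one-dimensional spaces.
    """
    va, vb = _basis(a), _basis(b)
    if va.shape[0] != vb.shape[0]:
        raise InvalidArgumentError("eigenspaces live on different node sets")
    s = np.linalg.svd(va.T @ vb, compute_uv=False)
    return float(np.clip(s, 0.0, 1.0).mean())


def similarity_matrix(spaces: list[ResponseEigenspace]) -> np.ndarray:
    """Pairwise similarity between all eigenspaces; symmetric, unit diagonal."""
    n = len(spaces)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = eigenspace_similarity(spaces[i], spaces[j])
    return sim


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    """Sum of squared distances to the assigned cluster centroid."""
    total = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return total


def _kmeans_labels(x: np.ndarray, k: int, seed: int) -> np.ndarray:
    if k == 1:
        return np.zeros(x.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed)
    return km.fit_predict(x)


def cluster_eigenspaces(
    sim: np.ndarray,
    k_max: int = 10,
    B_reference: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """k-means on the similarity-matrix rows, cluster count via the gap statistic.

    The gap statistic compares log within-cluster dispersion against B_reference
    uniform draws over the feature bounding box; the chosen k is the first with
    ``gap(k) >= gap(k+1) - s(k+1)`` (ties broken toward smaller k).
    """
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise InvalidArgumentError("similarity matrix must be square")
    if not np.allclose(sim, sim.T, atol=1e-9):
        raise InvalidArgumentError("similarity matrix must be symmetric")
    n = sim.shape[0]
    if k_max > n:
        log.warning("k_max=%d clipped to the %d available items", k_max, n)
        k_max = n
    if n == 1:
        return np.zeros(1, dtype=int), 1

    rng = np.random.default_rng(seed)
    x = sim
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)

    ks = list(range(1, k_max + 1))
    labels_by_k = {}
    log_w = np.empty(len(ks))
    gap = np.empty(len(ks))
    s_k = np.empty(len(ks))
    for i, k in enumerate(ks):
        labels_by_k[k] = _kmeans_labels(x, k, seed)
        w = max(_within_dispersion(x, labels_by_k[k]), 1e-300)
        log_w[i] = np.log(w)
        ref_logs = np.empty(B_reference)
        for b in range(B_reference):
            ref = lo + span * rng.random(x.shape)
            wb = max(_within_dispersion(ref, _kmeans_labels(ref, k, seed)), 1e-300)
            ref_logs[b] = np.log(wb)
        gap[i] = ref_logs.mean() - log_w[i]
        s_k[i] = ref_logs.std(ddof=0) * np.sqrt(1 + 1 / B_reference)

    chosen = ks[-1]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            chosen = ks[i]
            break
    return labels_by_k[chosen], chosen


def align_and_average(members: list[ResponseEigenspace | np.ndarray]) -> NetworkCluster:
    """Rotate cluster members onto the most central one and average the bases.

    The reference is the member with the highest mean similarity to the rest.
    Each member is mapped onto the reference with the orthogonal Procrustes
    rotation (SVD of the cross-product); the aligned bases are averaged
    elementwise and re-orthonormalized via SVD.  Members with more columns
    than the narrowest one are truncated to the common width.
    """
    if len(members) == 0:
        raise InvalidArgumentError("cannot average an empty cluster")
    bases = [_basis(m) for m in members]
    dim = {b.shape[0] for b in bases}
    if len(dim) != 1:
        raise InvalidArgumentError("members live on different node sets")
    k = min(b.shape[1] for b in bases)
    bases = [b[:, :k] for b in bases]
    conditions = [
        dict(m.condition) if isinstance(m, ResponseEigenspace) else {}
        for m in members
    ]
    if len(bases) == 1:
        return NetworkCluster(conditions, 0, canonical_sign(bases[0]))

    n = len(bases)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = eigenspace_similarity(bases[i], bases[j])
    ref_idx = int(np.argmax((sim.sum(axis=1) - 1.0) / (n - 1)))
    ref = bases[ref_idx]

    acc = np.zeros_like(ref)
    for b in bases:
        u, _, vt = np.linalg.svd(b.T @ ref)
        acc += b @ (u @ vt)
    acc /= n
    u, _, vt = np.linalg.svd(acc, full_matrices=False)
    mean = canonical_sign(u @ vt)
    cluster = NetworkCluster(conditions, ref_idx, mean)
    cluster.validate()
    return cluster


def repertoire_counts(
    spaces: list[ResponseEigenspace],
    k_max: int = 10,
    B_reference: int = 20,
    seed: int = 0,
    threshold: float = EFFECTIVE_SITE_THRESHOLD,
) -> tuple[int, int, np.ndarray, list[NetworkCluster]]:
    """Distinct-network and effective-site counts for one (alpha, sigma) condition.

    Returns (n_networks, n_effective_sites, labels, clusters).  A site counts
    as effective when its eigenspace has similarity >= threshold to the mean
    basis of its assigned cluster.
    """
    sim = similarity_matrix(spaces)
    labels, k = cluster_eigenspaces(sim, k_max=k_max, B_reference=B_reference, seed=seed)
    clusters = []
    effective = 0
    for lab in range(k):
        idx = np.where(labels == lab)[0]
        cluster = align_and_average([spaces[i] for i in idx])
        clusters.append(cluster)
        for i in idx:
            if eigenspace_similarity(spaces[i], cluster.mean_eigenvectors) >= threshold:
                effective += 1
    return k, effective, labels, clusters
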