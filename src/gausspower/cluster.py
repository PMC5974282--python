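"""Standardized eCDF profiles and k-means clustering with BIC selection.

A gene's replicate values are standardized to mean 0 / SD 1 and sorted
ascending; the sorted vector, paired with plotting positions (i-1)/(n-1),
is the gene's normalized empirical CDF profile.  Profiles within a
condition share the replicate count, so the sorted-value vectors are
directly comparable and are clustered with Euclidean k-means.  The number
of clusters minimizes an x-means-style BIC built from a spherical-Gaussian
cluster model.  Cluster-average profiles are shifted so their minimum is 0
(expression levels are nonnegative) before density estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "ECDFProfile",
    "ClusterModel",
    "ClusterProfile",
    "DegenerateGeneError",
    "build_ecdf_profile",
    "kmeans_bic",
    "select_k_and_fit",
    "cluster_average_profile",
]


class DegenerateGeneError(ValueError):
    """Raised for genes whose replicate values have zero variance."""


@dataclass(frozen=True)
class ECDFProfile:
    """Sorted standardized replicate values with plotting positions."""

    values: np.ndarray    # ascending; mean 0, sample SD 1 pre-sorting
    positions: np.ndarray  # (i-1)/(n-1), strictly increasing, 0..1
    gene_id: str | None = None
    condition: str | None = None


@dataclass(frozen=True)
class ClusterModel:
    k: int
    centroids: np.ndarray       # (k, d)
    assignments: np.ndarray     # (n,)
    inertia: float
    bic: float
    bic_by_k: dict


@dataclass(frozen=True)
class ClusterProfile:
    """Average sorted-value vector of one cluster, shifted to min = 0."""

    cluster_id: int
    values: np.ndarray
    positions: np.ndarray
    n_members: int


def build_ecdf_profile(values, gene_id: str | None = None,
                       condition: str | None = None) -> ECDFProfile:
    """Standardize (n-1 denominator), sort ascending, attach positions."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need >= 2 replicate values")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateGeneError(
            f"gene {gene_id!r}: zero variance across replicates")
    z = np.sort((v - v.mean()) / sd)
    pos = np.arange(v.size) / (v.size - 1)
    return ECDFProfile(values=z, positions=pos, gene_id=gene_id,
                       condition=condition)


def kmeans_bic(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray,
               inertia: float) -> float:
    """x-means BIC of a fitted k-means under a spherical-Gaussian mixture.

    BIC = -2 lnL + p ln n with the Pelleg-Moore log-likelihood
    lnL = sum_j n_j ln(n_j/n) - (n d / 2) ln(2 pi sigma^2) - d (n - k) / 2,
    sigma^2 = inertia / (d (n - k)) and p = (k - 1) + k d + 1 free
    parameters (mixture weights, centroids, shared variance).  The
    mixture-weight term is what keeps homogeneous data at k = 1.
    Lower is better.
    """
    n, d = X.shape
    k = centroids.shape[0]
    if n <= k:
        return np.inf
    sigma2 = max(inertia / (d * (n - k)), 1e-300)
    counts = np.bincount(labels, minlength=k).astype(float)
    counts = counts[counts > 0]
    loglik = (float(np.sum(counts * np.log(counts / n)))
              - 0.5 * n * d * np.log(2.0 * np.pi * sigma2)
              - 0.5 * d * (n - k))
    p = (k - 1) + k * d + 1
    return -2.0 * loglik + p * np.log(n)


def select_k_and_fit(profiles, k_range=(2, 20), seed: int = 0,
                     n_restarts: int = 10) -> ClusterModel:
    """Fit k-means for each k in the inclusive range; keep the BIC minimum.

    ``profiles`` is a sequence of :class:`ECDFProfile` of equal length or
    a 2-D array.  Deterministic given ``seed``.
    """
    if hasattr(profiles[0], "values"):
        lengths = {p.values.size for p in profiles}
        if len(lengths) > 1:
            raise ValueError(f"profiles have mixed lengths {sorted(lengths)}")
        X = np.vstack([p.values for p in profiles])
    else:
        X = np.asarray(profiles, dtype=float)
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo < 1 or k_hi < k_lo:
        raise ValueError(f"bad k_range {k_range}")
    if k_hi >= X.shape[0]:
        raise ValueError(
            f"k_range max {k_hi} must be < number of profiles {X.shape[0]}")
    best = None
    bic_by_k = {}
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        bic = kmeans_bic(X, labels, km.cluster_centers_, km.inertia_)
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, km.cluster_centers_, labels, km.inertia_)
    bic, k, centroids, labels, inertia = best
    return ClusterModel(k=k, centroids=centroids, assignments=labels,
                        inertia=float(inertia), bic=float(bic),
                        bic_by_k=bic_by_k)


def cluster_average_profile(model: ClusterModel, profiles,
                            cluster_id: int) -> ClusterProfile:
    """Componentwise mean of member profiles, shifted so min = 0."""
    members = [p for p, a in zip(profiles, model.assignments)
               if a == cluster_id]
    if not members:
        raise ValueError(f"cluster {cluster_id} is empty")
    mean = np.mean([p.values for p in members], axis=0)
    shifted = mean - mean.min()
    return ClusterProfile(cluster_id=int(cluster_id), values=shifted,
                          positions=members[0].positions.copy(),
                          n_members=len(members))
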