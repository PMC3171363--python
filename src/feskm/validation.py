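"""Cluster-quality statistics: within-class variance (SSE), mean square
error on a decibel scale, and the Davies-Bouldin validity index.

The Davies-Bouldin index is the mean, over clusters, of the worst-case
similarity ratio (e_i + e_j) / D_ij, where e_i is a cluster's average
(plain, not squared) Euclidean distance of members to its center and D_ij is
the Euclidean distance between the two centers.  Lower is better; compact,
well-separated sphere-like clusters score near zero.  Dead (empty) clusters
are excluded from the sum with a warning and k is reduced accordingly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .clustering import CenterSet
from .kdtree import PointSet

__all__ = ["DBIReport", "sse", "mse_db", "cluster_dispersion", "davies_bouldin"]


class DegenerateMSEError(ValueError):
    """Raised when SSE is exactly zero and no finite dB value exists."""


def _check(points: PointSet, assignments, centers: CenterSet) -> np.ndarray:
    labels = np.asarray(assignments)
    if labels.shape != (points.n,):
        raise ValueError("assignments must carry one label per record")
    if labels.min() < 0 or labels.max() >= centers.k:
        raise ValueError("assignment label out of range for the given centers")
    if centers.dim != points.dim:
        raise ValueError("center dimension does not match points")
    return labels


def sse(points: PointSet, assignments, centers: CenterSet) -> float:
    """Within-class variance: sum of squared Euclidean distances of each
    record to its assigned center."""
    labels = _check(points, assignments, centers)
    diff = points.coords - centers.centers[labels]
    return float((diff * diff).sum())


def mse_db(points: PointSet, assignments, centers: CenterSet) -> float:
    """Mean square error in decibels: 10*log10(SSE / N)."""
    s = sse(points, assignments, centers)
    if s == 0.0:
        raise DegenerateMSEError("SSE is zero; MSE has no finite dB value")
    return 10.0 * math.log10(s / points.n)


def cluster_dispersion(member_coords, center) -> float:
    """Average Euclidean distance of a cluster's members to its center."""
    member_coords = np.atleast_2d(np.asarray(member_coords, dtype=float))
    if member_coords.shape[0] == 0:
        raise ValueError("cluster_dispersion of an empty cluster is undefined")
    center = np.asarray(center, dtype=float)
    return float(np.sqrt(((member_coords - center) ** 2).sum(axis=1)).mean())


@dataclass
class DBIReport:
    dispersions: np.ndarray        # (k,) e_i; NaN for dead clusters
    center_distances: np.ndarray   # (k, k) D_ij
    pairwise_ratios: np.ndarray    # (k, k) (e_i+e_j)/D_ij; NaN off the live set
    index: float
    alive: np.ndarray              # (k,) bool
    dead_centers: list[int]


def davies_bouldin(points: PointSet, assignments, centers: CenterSet) -> DBIReport:
    """Davies-Bouldin index with all intermediate quantities.

    Requires at least two non-empty clusters with pairwise-distinct centers.
    """
    labels = _check(points, assignments, centers)
    k = centers.k
    counts = np.bincount(labels, minlength=k)
    alive = counts > 0
    dead = [int(i) for i in np.flatnonzero(~alive)]
    if dead:
        warnings.warn(
            f"excluding {len(dead)} dead cluster(s) {dead} from the Davies-Bouldin index",
            stacklevel=2,
        )
    if alive.sum() < 2:
        raise ValueError("Davies-Bouldin index needs at least two non-empty clusters")
    e = np.full(k, np.nan)
    for i in np.flatnonzero(alive):
        e[i] = cluster_dispersion(points.coords[labels == i], centers.centers[i])
    D = cdist(centers.centers, centers.centers)
    live = np.flatnonzero(alive)
    off = D[np.ix_(live, live)][~np.eye(live.size, dtype=bool)]
    if np.any(off == 0.0):
        raise ValueError("coincident centers of non-empty clusters: D_ij = 0")
    ratios = np.full((k, k), np.nan)
    for i in live:
        for j in live:
            if i != j:
                ratios[i, j] = (e[i] + e[j]) / D[i, j]
    index = float(np.mean([np.nanmax(ratios[i, live]) for i in live]))
    return DBIReport(e, D, ratios, index, alive, dead)
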