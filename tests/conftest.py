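"""Shared fixtures and independent reference implementations.

The references here are deliberately naive (linear scans, explicit loops)
and are kept independent of the package's accelerated code paths so they can
serve as oracles.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from feskm.kdtree import PointSet


# ---------------------------------------------------------------------------
# brute-force references


def brute_nearest(coords: np.ndarray, query: np.ndarray) -> tuple[int, float]:
    """Linear-scan nearest neighbor; ties to the lowest index."""
    d2 = ((coords - query) ** 2).sum(axis=1)
    idx = int(np.argmin(d2))
    return idx, math.sqrt(float(d2[idx]))


def brute_assign(coords: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Brute-force nearest-center labels; ties to the lowest center index."""
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def brute_fes(coords: np.ndarray, k: int, eta0: float, epsilon: float,
              max_iter: int, seed: int):
    """Standalone sequential FES run: brute-force nearest-center search,
    per-epoch decaying rate, stopping on the displacement test, MSE
    stability, or the iteration cap.  Returns (labels, centers, eta_trace,
    mse_trace)."""
    n = coords.shape[0]
    rng = np.random.default_rng(seed)
    centers = coords[rng.choice(n, size=k, replace=False)].copy()
    eta = eta0
    eta_trace, mse_trace = [], []
    prev_labels = None
    prev_mse = None
    for t in range(1, max_iter + 1):
        start = centers.copy()
        for i in range(n):
            x = coords[i]
            diff = centers - x
            j = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            centers[j] += eta * (x - centers[j])
        shift = float(np.sqrt(((centers - start) ** 2).sum(axis=1)).max())
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        mse = float(((coords - centers[labels]) ** 2).sum()) / n
        eta_trace.append(eta)
        mse_trace.append(mse)
        stop = shift < epsilon or (
            prev_mse is not None and abs(mse - prev_mse) <= 1e-8 * max(prev_mse, 1e-300)
        )
        prev_labels, prev_mse = labels, mse
        eta = eta * math.exp(-1.0 / math.sqrt(k + t))
        if stop:
            break
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    return labels, centers, eta_trace, mse_trace


def reference_dbi(coords: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Naive loop implementation of the Davies-Bouldin index for arbitrary
    (non-centroid) centers; empty clusters excluded."""
    k = centers.shape[0]
    live = [i for i in range(k) if np.any(labels == i)]
    e = {}
    for i in live:
        pts = coords[labels == i]
        e[i] = float(np.mean([math.dist(p, centers[i]) for p in pts]))
    total = 0.0
    for i in live:
        worst = -math.inf
        for j in live:
            if j == i:
                continue
            dij = math.dist(centers[i], centers[j])
            worst = max(worst, (e[i] + e[j]) / dij)
        total += worst
    return total / len(live)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def two_blobs(rng) -> tuple[PointSet, np.ndarray]:
    """Two well-separated planar Gaussian blobs (means (0,0) and (20,20))."""
    a = rng.normal((0.0, 0.0), 1.0, size=(200, 2))
    b = rng.normal((20.0, 20.0), 1.0, size=(200, 2))
    coords = np.vstack([a, b])
    labels = np.repeat([0, 1], 200)
    return PointSet.from_array(coords), labels
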