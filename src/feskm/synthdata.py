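"""Seeded synthetic geospatial point generators.

The generator emulates the structure of the study datasets this package
targets: planar Gaussian clusters of equal size, optionally with a density
gradient (clusters far from the origin are more spread out than those near
it) and with appended 0/1 indicator columns mimicking binary exposure flags
attached to point locations.

Two placement modes exist.  In the default *separable* mode cluster centers
are drawn in ``center_box`` subject to a minimum pairwise separation of six
within-cluster standard deviations, so ground truth is recoverable and the
generator doubles as a test oracle.  The *hard* mode drops the separation
constraint, producing clusters that run into each other at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kdtree import PointSet

__all__ = ["SyntheticSpec", "generate"]

#: minimum center separation in units of the largest within-cluster sd
SEPARATION_FACTOR = 6.0


@dataclass(frozen=True)
class SyntheticSpec:
    n_clusters: int = 10
    points_per_cluster: int = 3600
    dim: int = 2
    center_box: tuple[float, float] = (0.0, 100.0)
    base_spread: float = 1.0
    density_gradient: bool = False
    separable: bool = True
    binary_dims: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.points_per_cluster < 1 or self.dim < 1:
            raise ValueError("n_clusters, points_per_cluster and dim must be >= 1")
        if self.base_spread <= 0:
            raise ValueError("base_spread must be positive")
        if self.binary_dims < 0:
            raise ValueError("binary_dims must be >= 0")
        lo, hi = self.center_box
        if not lo < hi:
            raise ValueError("center_box must be an interval (lo, hi) with lo < hi")

    @property
    def n_total(self) -> int:
        return self.n_clusters * self.points_per_cluster


def _draw_centers(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.center_box
    if not spec.separable:
        return rng.uniform(lo, hi, size=(spec.n_clusters, spec.dim))
    # gradient inflates sd by up to 1.5x; keep separation relative to the max
    max_sd = spec.base_spread * (1.5 if spec.density_gradient else 1.0)
    min_sep = SEPARATION_FACTOR * max_sd
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 10000 * spec.n_clusters
    while len(centers) < spec.n_clusters:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not place separated cluster centers in center_box; "
                "enlarge the box or reduce base_spread / n_clusters"
            )
        cand = rng.uniform(lo, hi, size=spec.dim)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    return np.vstack(centers)


def generate(spec: SyntheticSpec) -> tuple[PointSet, np.ndarray]:
    """Generate a labeled point set according to ``spec``.

    Returns the :class:`PointSet` (Gaussian coordinate columns followed by
    any binary indicator columns) and the ground-truth labels.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _draw_centers(spec, rng)
    if spec.density_gradient:
        r = np.linalg.norm(centers, axis=1)
        r_max = r.max() if r.max() > 0 else 1.0
        sds = spec.base_spread * (0.5 + r / r_max)
    else:
        sds = np.full(spec.n_clusters, spec.base_spread)
    m = spec.points_per_cluster
    blocks = [
        centers[c] + rng.normal(0.0, sds[c], size=(m, spec.dim))
        for c in range(spec.n_clusters)
    ]
    coords = np.vstack(blocks)
    labels = np.repeat(np.arange(spec.n_clusters), m)
    names = [f"x{i}" for i in range(spec.dim)]
    if spec.binary_dims:
        # per-cluster Bernoulli probabilities so indicators carry cluster signal
        probs = rng.uniform(0.1, 0.9, size=(spec.n_clusters, spec.binary_dims))
        flags = rng.binomial(1, probs[labels]).astype(float)
        coords = np.hstack([coords, flags])
        names += [f"b{i}" for i in range(spec.binary_dims)]
    ids = np.arange(coords.shape[0])
    return PointSet(coords, ids, tuple(names)), labels
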