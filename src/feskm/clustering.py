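"""k-means variants: batch (Lloyd), online (MacQueen), and the tree-filtered
online variant with a decaying adaptation rate ("FES" k-means).

All three share the same initialization (k distinct records drawn uniformly
from the data), convergence tests (stable membership, maximum per-center
displacement below ``epsilon``, relative MSE change below 1e-8, or the
iteration cap) and result container.

The FES variant presents every vector once per epoch, moves the winning
center by ``eta * (x - c)``, and shrinks ``eta`` once per epoch by the
schedule ``eta <- eta * exp(-1 / sqrt(k + t))`` — a large clustering rate at
the start of training decaying to a small steady-state value.  Its
nearest-center searches are accelerated with the k-d tree but are
contractually identical to brute-force sequential search: a best-two
filtering pass at epoch start gives each point's nearest and second-nearest
center distances (d1, d2) under the epoch-start centers, and while centers
drift during the epoch only "suspect" centers — those whose drift exceeds
d2 - d1 - drift(winner) — can possibly have overtaken the point's
epoch-start winner (triangle inequality), so only they are re-evaluated.
The bound is lossless, so labels, centers and traces match the brute-force
path bitwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .kdtree import PointSet, build_kdtree, filter_assign, filter_best2

__all__ = [
    "CenterSet",
    "AdaptationState",
    "RunConfig",
    "ClusteringResult",
    "init_centers",
    "lloyd_kmeans",
    "macqueen_kmeans",
    "fes_kmeans",
    "mashor_eta_update",
    "fes_update_center",
    "run",
]

logger = logging.getLogger("feskm")

METHODS = ("lloyd", "macqueen", "fes")

#: relative MSE change below which training is declared stable
MSE_STABILITY_RTOL = 1e-8


@dataclass
class CenterSet:
    """The k cluster centers as a k x d matrix."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if c.shape[0] < 1 or not np.all(np.isfinite(c)):
            raise ValueError("centers must be a nonempty finite k x d matrix")
        self.centers = c

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def dim(self) -> int:
        return self.centers.shape[1]


@dataclass(frozen=True)
class AdaptationState:
    """State of the decaying adaptation-rate schedule.

    ``eta`` is the current step size (0 < eta <= 1), ``iter`` the epoch
    counter (starting at 1), ``cluster_count`` the number of clusters k.
    """

    eta: float
    iter: int = 1
    cluster_count: int = 1


def mashor_eta_update(state: AdaptationState) -> AdaptationState:
    """One step of the decaying schedule: eta' = eta * exp(-1/sqrt(k + t)).

    The rate decreases strictly at every step but the decay slows as t grows,
    leaving a small steady-state step size late in training.
    """
    if not (0 < state.eta <= 1):
        raise ValueError("adaptation rate must lie in (0, 1]")
    if state.iter < 1 or state.cluster_count < 1:
        raise ValueError("iter and cluster_count must be >= 1")
    eta = state.eta * math.exp(-1.0 / math.sqrt(state.cluster_count + state.iter))
    return AdaptationState(eta=eta, iter=state.iter + 1, cluster_count=state.cluster_count)


def macqueen_update_center(center, point, n_wins: int) -> tuple[np.ndarray, int]:
    """MacQueen's variable-rate step: the winning center, having won
    ``n_wins`` points so far (including its initializing record), absorbs a
    new point and moves to the running mean of its n_wins + 1 wins."""
    if n_wins < 1:
        raise ValueError("n_wins must count the initializing record (>= 1)")
    center = np.asarray(center, dtype=float)
    point = np.asarray(point, dtype=float)
    if center.shape != point.shape:
        raise ValueError("center and point dimensions differ")
    n = n_wins + 1
    return center + (point - center) / n, n


def fes_update_center(center, point, eta: float) -> np.ndarray:
    """Move a center toward a presented point: c' = c + eta * (x - c)."""
    if not (0.0 <= eta <= 1.0):
        raise ValueError("eta must lie in [0, 1]")
    center = np.asarray(center, dtype=float)
    point = np.asarray(point, dtype=float)
    if center.shape != point.shape:
        raise ValueError("center and point dimensions differ")
    return center + eta * (point - center)


@dataclass(frozen=True)
class RunConfig:
    """Configuration shared by the three methods.

    epsilon is the convergence tolerance on the maximum per-center
    displacement in one epoch; eta0 the initial adaptation rate (FES only).
    """

    k: int
    eta0: float = 0.6
    epsilon: float = 1e-4
    max_iter: int = 20
    seed: int = 0
    shuffle: bool = False
    method: str = "fes"
    leaf_size: int = 10
    reseed_dead: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.eta0 <= 1):
            raise ValueError("eta0 must lie in (0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")


@dataclass
class ClusteringResult:
    assignments: np.ndarray
    centers: CenterSet
    n_iter: int
    mse_trace: list[float]
    converged: bool
    reason: str
    eta_trace: list[float] | None = None
    dead_centers: list[int] = field(default_factory=list)
    n_dist_evals: int = 0


def init_centers(points: PointSet, k: int, seed: int) -> CenterSet:
    """Draw k distinct records uniformly without replacement as initial centers."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > points.n:
        raise ValueError(f"k={k} exceeds the number of records N={points.n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(points.n, size=k, replace=False)
    return CenterSet(points.coords[idx].copy())


def _assign_full(coords: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Brute-force nearest-center labels (ties -> lowest center index)."""
    d2 = cdist(coords, centers, metric="sqeuclidean")
    return np.argmin(d2, axis=1)


def _mse(coords: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    diff = coords - centers[labels]
    return float((diff * diff).sum()) / coords.shape[0]


def _mse_db_or_nan(mse: float) -> float:
    return 10.0 * math.log10(mse) if mse > 0 else float("nan")


def _reseed_dead_centers(coords, centers, counts) -> None:
    """Relocate each empty center to the point farthest from its nearest center."""
    for c in np.flatnonzero(counts == 0):
        d2 = cdist(coords, centers, metric="sqeuclidean").min(axis=1)
        centers[c] = coords[int(np.argmax(d2))]


def _check_converged(prev_labels, labels, shift, prev_mse, mse, epsilon,
                     use_membership=True):
    """Shared convergence tests.

    Membership stability is an exact convergence certificate only for the
    batch method; online updates keep jittering centers by O(eta) after the
    partition settles, so the online methods rely on the displacement and
    MSE tests (and the iteration cap) instead.
    """
    if use_membership and prev_labels is not None and np.array_equal(prev_labels, labels):
        return "membership_stable"
    if shift < epsilon:
        return "center_shift"
    if prev_mse is not None and abs(mse - prev_mse) <= MSE_STABILITY_RTOL * max(prev_mse, 1e-300):
        return "mse_stable"
    return None


def _finalize(points, centers, labels, n_iter, mse_trace, reason, eta_trace=None, evals=0):
    counts = np.bincount(labels, minlength=centers.shape[0])
    dead = [int(i) for i in np.flatnonzero(counts == 0)]
    return ClusteringResult(
        assignments=labels,
        centers=CenterSet(centers),
        n_iter=n_iter,
        mse_trace=mse_trace,
        converged=reason != "max_iter",
        reason=reason,
        eta_trace=eta_trace,
        dead_centers=dead,
        n_dist_evals=evals,
    )


def lloyd_kmeans(points: PointSet, config: RunConfig) -> ClusteringResult:
    """Batch k-means: alternate full reassignment and centroid recomputation.

    The recorded MSE trace is non-increasing (each epoch's reassignment and
    centroid step both lower the within-class variance).
    """
    coords = points.coords
    centers = init_centers(points, config.k, config.seed).centers.copy()
    mse_trace: list[float] = []
    prev_labels = None
    prev_mse = None
    evals = 0
    reason = "max_iter"
    labels = None
    for epoch in range(1, config.max_iter + 1):
        labels = _assign_full(coords, centers)
        evals += coords.shape[0] * config.k
        counts = np.bincount(labels, minlength=config.k)
        if config.reseed_dead and np.any(counts == 0):
            _reseed_dead_centers(coords, centers, counts)
            labels = _assign_full(coords, centers)
            counts = np.bincount(labels, minlength=config.k)
        sums = np.zeros_like(centers)
        np.add.at(sums, labels, coords)
        new_centers = np.where(counts[:, None] > 0, sums / np.maximum(counts, 1)[:, None], centers)
        shift = float(np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max())
        centers = new_centers
        mse = _mse(coords, centers, labels)
        mse_trace.append(mse)
        logger.info(
            "method=lloyd epoch=%d mse_db=%.6f max_shift=%.3e", epoch, _mse_db_or_nan(mse), shift
        )
        stop = _check_converged(prev_labels, labels, shift, prev_mse, mse, config.epsilon)
        prev_labels, prev_mse = labels, mse
        if stop:
            reason = stop
            break
    labels = _assign_full(coords, centers)
    return _finalize(points, centers, labels, len(mse_trace), mse_trace, reason, evals=evals)


def macqueen_kmeans(points: PointSet, config: RunConfig) -> ClusteringResult:
    """Online k-means with the 1/n variable rate.

    On presenting x, the winning center i moves by (1/n_i)(x - c_i) where n_i
    counts every win including the record that initialized the center, so a
    center always equals the running mean of the points it has won.
    """
    coords = points.coords
    n, k = points.n, config.k
    centers = init_centers(points, k, config.seed).centers.copy()
    wins = np.ones(k)  # the initializing record counts as the first win
    order_rng = np.random.default_rng([config.seed, 1])
    mse_trace: list[float] = []
    prev_labels = None
    prev_mse = None
    evals = 0
    reason = "max_iter"
    for epoch in range(1, config.max_iter + 1):
        order = order_rng.permutation(n) if config.shuffle else np.arange(n)
        start = centers.copy()
        for i in order:
            x = coords[i]
            diff = centers - x
            j = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            evals += k
            wins[j] += 1.0
            centers[j] += (x - centers[j]) / wins[j]  # MacQueen 1/n step
        shift = float(np.sqrt(((centers - start) ** 2).sum(axis=1)).max())
        labels = _assign_full(coords, centers)
        evals += n * k
        counts = np.bincount(labels, minlength=k)
        if config.reseed_dead and np.any(counts == 0):
            _reseed_dead_centers(coords, centers, counts)
            labels = _assign_full(coords, centers)
        mse = _mse(coords, centers, labels)
        mse_trace.append(mse)
        logger.info(
            "method=macqueen epoch=%d mse_db=%.6f max_shift=%.3e",
            epoch, _mse_db_or_nan(mse), shift,
        )
        stop = _check_converged(prev_labels, labels, shift, prev_mse, mse,
                                config.epsilon, use_membership=False)
        prev_labels, prev_mse = labels, mse
        if stop:
            reason = stop
            break
    labels = _assign_full(coords, centers)
    return _finalize(points, centers, labels, len(mse_trace), mse_trace, reason, evals=evals)


def fes_kmeans(points: PointSet, config: RunConfig, use_tree: bool = True) -> ClusteringResult:
    """Tree-filtered online k-means with the decaying adaptation rate.

    With ``use_tree=False`` the same sequential algorithm runs with
    brute-force nearest-center search; both paths produce bitwise-identical
    assignments, centers, eta and MSE traces.
    """
    coords = points.coords
    n, k = points.n, config.k
    centers = init_centers(points, k, config.seed).centers.copy()
    tree = build_kdtree(points, config.leaf_size) if use_tree else None
    span = float((coords.max(axis=0) - coords.min(axis=0)).max())
    slack = 1e-9 * max(span, 1.0)  # guards fast-path decisions against rounding
    state = AdaptationState(eta=config.eta0, iter=1, cluster_count=k)
    order_rng = np.random.default_rng([config.seed, 1])
    mse_trace: list[float] = []
    eta_trace: list[float] = []
    prev_labels = None
    prev_mse = None
    evals = 0
    reason = "max_iter"
    for epoch in range(1, config.max_iter + 1):
        eta = state.eta
        order = order_rng.permutation(n) if config.shuffle else np.arange(n)
        start = centers.copy()
        if use_tree and k >= 2:
            labels0, d1, d2, e = filter_best2(tree, centers)
            evals += e
        drift = np.zeros(k)
        for i in order:
            x = coords[i]
            if use_tree and k == 1:
                j = 0
            elif use_tree:
                w0 = int(labels0[i])
                # centers that cannot have overtaken the epoch-start winner
                # are excluded by the triangle inequality (lossless)
                mask = drift > (d2[i] - d1[i] - drift[w0]) - slack
                mask[w0] = True
                cand = np.flatnonzero(mask)
                if cand.size == 1:
                    j = w0
                else:
                    diff = centers[cand] - x
                    j = int(cand[np.argmin(np.einsum("ij,ij->i", diff, diff))])
                    evals += cand.size
            else:
                diff = centers - x
                j = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
                evals += k
            centers[j] += eta * (x - centers[j])
            if use_tree:
                drift[j] = float(np.sqrt(((centers[j] - start[j]) ** 2).sum()))
        shift = float(np.sqrt(((centers - start) ** 2).sum(axis=1)).max())
        if use_tree:
            fr = filter_assign(tree, centers)
            labels = fr.assignments
            evals += fr.n_dist_evals
        else:
            labels = _assign_full(coords, centers)
            evals += n * k
        counts = np.bincount(labels, minlength=k)
        if config.reseed_dead and np.any(counts == 0):
            _reseed_dead_centers(coords, centers, counts)
            labels = filter_assign(tree, centers).assignments if use_tree else _assign_full(coords, centers)
        mse = _mse(coords, centers, labels)
        mse_trace.append(mse)
        eta_trace.append(eta)
        logger.info(
            "method=fes epoch=%d eta=%.6f mse_db=%.6f max_shift=%.3e",
            epoch, eta, _mse_db_or_nan(mse), shift,
        )
        stop = _check_converged(prev_labels, labels, shift, prev_mse, mse,
                                config.epsilon, use_membership=False)
        prev_labels, prev_mse = labels, mse
        state = mashor_eta_update(state)
        if stop:
            reason = stop
            break
    labels = filter_assign(tree, centers).assignments if use_tree else _assign_full(coords, centers)
    return _finalize(
        points, centers, labels, len(mse_trace), mse_trace, reason, eta_trace=eta_trace, evals=evals
    )


def run(points: PointSet, config: RunConfig) -> ClusteringResult:
    """Dispatch on ``config.method``."""
    if config.method == "lloyd":
        return lloyd_kmeans(points, config)
    if config.method == "macqueen":
        return macqueen_kmeans(points, config)
    return fes_kmeans(points, config)
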