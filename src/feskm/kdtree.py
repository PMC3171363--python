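"""Multidimensional binary search tree with midpoint-on-longest-side splits.

The tree recursively subdivides the data space by axis-aligned hyperplanes.
Each internal node splits its cell's longest side at the midpoint (sliding to
the median coordinate if a midpoint split would leave a child empty, so that
every splitting hyperplane separates the node's points into two nonempty
groups).  Nodes carry per-subtree sufficient statistics (point count and
coordinate sum) which allow whole cells to be assigned to a cluster center in
bulk during the filtering pass.

Candidate pruning during filtering follows the bisecting-hyperplane rule: a
candidate center is discarded for a cell as soon as no point of the cell's
bounding box can be strictly closer to it than to the cell's current winning
candidate.  Pruning is lossless, so filtered assignments are identical to
brute-force nearest-center assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "PointSet",
    "KDNode",
    "KDTree",
    "FilterResult",
    "build_kdtree",
    "nearest_neighbor",
    "prune_candidate",
    "filter_assign",
]


@dataclass(frozen=True)
class PointSet:
    """An N x d block of numeric records with unique identifiers.

    Parameters
    ----------
    coords : ndarray, shape (N, d)
        Coordinates / attributes, all finite.
    ids : ndarray, shape (N,)
        Unique record identifiers (any hashable dtype).
    dim_names : tuple of str, optional
        Labels for the d feature columns.
    """

    coords: np.ndarray
    ids: np.ndarray
    dim_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise ValueError("coords must be a 2-D array (N x d)")
        if coords.shape[0] < 1 or coords.shape[1] < 1:
            raise ValueError("PointSet requires N >= 1 and d >= 1")
        if not np.all(np.isfinite(coords)):
            raise ValueError("all coordinates must be finite")
        ids = np.asarray(self.ids)
        if ids.shape != (coords.shape[0],):
            raise ValueError("ids must have one entry per row")
        if len(set(ids.tolist())) != ids.shape[0]:
            raise ValueError("record ids must be unique")
        if self.dim_names is not None and len(self.dim_names) != coords.shape[1]:
            raise ValueError("dim_names must have one label per column")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "ids", ids)

    @classmethod
    def from_array(cls, coords, ids=None, dim_names=None) -> "PointSet":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
        if ids is None:
            ids = np.arange(coords.shape[0])
        return cls(coords, np.asarray(ids), dim_names)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclass
class KDNode:
    """One cell of the subdivision.

    ``bbox_lo``/``bbox_hi`` are the tight bounds of the points in the cell
    (closed box).  Leaves own a contiguous slice [start, end) of the tree's
    index permutation; internal nodes carry the split and two children.
    ``count`` and ``vector_sum`` aggregate the whole subtree.
    """

    bbox_lo: np.ndarray
    bbox_hi: np.ndarray
    start: int
    end: int
    count: int
    vector_sum: np.ndarray
    split_dim: int | None = None
    split_val: float | None = None
    left: "KDNode | None" = None
    right: "KDNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class KDTree:
    root: KDNode
    leaf_size: int
    points: PointSet
    # permutation of 0..N-1; each node owns a contiguous slice of it
    index: np.ndarray = field(repr=False, default=None)

    @property
    def dim(self) -> int:
        return self.points.dim

    def subtree_indices(self, node: KDNode) -> np.ndarray:
        return self.index[node.start:node.end]


def build_kdtree(points: PointSet, leaf_size: int = 10) -> KDTree:
    """Build the tree by recursive midpoint splits along the longest side.

    Splitting stops when a cell holds at most ``leaf_size`` points or all of
    its points coincide.  Ties between equally long sides go to the lowest
    dimension index; points lying exactly on a splitting plane go to the left
    child.
    """
    if not isinstance(points, PointSet):
        points = PointSet.from_array(points)
    if leaf_size < 1:
        raise ValueError("leaf_size must be >= 1")
    coords = points.coords
    index = np.arange(points.n)

    def recurse(start: int, end: int) -> KDNode:
        idx = index[start:end]
        pts = coords[idx]
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        node = KDNode(lo, hi, start, end, end - start, pts.sum(axis=0))
        side = hi - lo
        if end - start <= leaf_size or not np.any(side > 0):
            return node
        dim = int(np.argmax(side))  # argmax takes the lowest index on ties
        split = 0.5 * (lo[dim] + hi[dim])
        mask = pts[:, dim] <= split
        if not mask.any() or mask.all():
            # floating-point degenerate midpoint: slide to the median
            split = float(np.median(pts[:, dim]))
            mask = pts[:, dim] <= split
            if not mask.any() or mask.all():
                return node  # cannot separate; keep as (oversized) leaf
        # rearrange the slice so children own contiguous ranges
        order = np.argsort(~mask, kind="stable")
        index[start:end] = idx[order]
        n_left = int(mask.sum())
        node.split_dim = dim
        node.split_val = float(split)
        node.left = recurse(start, start + n_left)
        node.right = recurse(start + n_left, end)
        return node

    root = recurse(0, points.n)
    return KDTree(root=root, leaf_size=leaf_size, points=points, index=index)


def _min_sqdist_to_box(lo: np.ndarray, hi: np.ndarray, q: np.ndarray) -> float:
    d = np.maximum(np.maximum(lo - q, q - hi), 0.0)
    return float(d @ d)


def nearest_neighbor(tree: KDTree, query) -> tuple[int, float]:
    """Exact nearest data point to ``query`` (Euclidean; ties -> lowest index).

    Returns ``(index, distance)`` where ``index`` is a row index into the
    tree's :class:`PointSet`.
    """
    query = np.asarray(query, dtype=float).ravel()
    if query.shape[0] != tree.dim:
        raise ValueError(
            f"query dimension {query.shape[0]} does not match tree dimension {tree.dim}"
        )
    coords = tree.points.coords
    best_sq = np.inf
    best_idx = -1

    def visit(node: KDNode) -> None:
        nonlocal best_sq, best_idx
        if node.is_leaf:
            idx = tree.subtree_indices(node)
            diff = coords[idx] - query
            sq = np.einsum("ij,ij->i", diff, diff)
            for pos in np.flatnonzero(sq <= min(best_sq, sq.min())):
                d2, i = sq[pos], int(idx[pos])
                if d2 < best_sq or (d2 == best_sq and i < best_idx):
                    best_sq, best_idx = d2, i
            return
        near, far = node.left, node.right
        if query[node.split_dim] > node.split_val:
            near, far = far, near
        if _min_sqdist_to_box(near.bbox_lo, near.bbox_hi, query) <= best_sq:
            visit(near)
        # non-strict bound so equal-distance points keep lowest-index wins
        if _min_sqdist_to_box(far.bbox_lo, far.bbox_hi, query) <= best_sq:
            visit(far)

    visit(tree.root)
    return best_idx, float(np.sqrt(best_sq))


def _prune_margin(bbox_lo, bbox_hi, candidate, winner) -> float:
    """min over box points p of ||p-candidate||^2 - ||p-winner||^2.

    The minimum of this linear-in-p expression is attained at the box corner
    extremal in the direction candidate - winner.
    """
    u = candidate - winner
    corner = np.where(u > 0, bbox_hi, bbox_lo)
    return float(u @ (candidate + winner - 2.0 * corner))


def prune_candidate(bbox_lo, bbox_hi, candidate, winner) -> bool:
    """True iff no point of the closed box is strictly closer to ``candidate``
    than to ``winner`` — i.e. the candidate can be discarded for the cell."""
    bbox_lo = np.asarray(bbox_lo, dtype=float)
    bbox_hi = np.asarray(bbox_hi, dtype=float)
    if bbox_lo.shape != bbox_hi.shape or np.any(bbox_lo > bbox_hi):
        raise ValueError("invalid box: need bbox_lo <= bbox_hi componentwise")
    candidate = np.asarray(candidate, dtype=float)
    winner = np.asarray(winner, dtype=float)
    return _prune_margin(bbox_lo, bbox_hi, candidate, winner) >= 0.0


def _dominates(node: KDNode, centers: np.ndarray, a: int, b: int) -> bool:
    """Center ``a`` strictly beats center ``b`` on every point of the node's
    box, by more than a conservative floating-point error bound.

    Near-ties are deliberately NOT pruned: they are left for the leaf scan,
    which uses the same distance arithmetic as a brute-force pass and so
    resolves them (including the lowest-index rule) exactly as brute force
    would.  Coincident centers fall out the same way (zero margin, kept).
    """
    ca, cb = centers[a], centers[b]
    u = cb - ca
    corner = np.where(u > 0, node.bbox_hi, node.bbox_lo)
    v = cb + ca - 2.0 * corner
    margin = float(u @ v)
    err = 1e-12 * float(np.abs(u) @ np.abs(v)) + 1e-300
    return margin > err


@dataclass
class FilterResult:
    assignments: np.ndarray          # (N,) center labels
    counts: np.ndarray               # (k,) member counts
    vector_sums: np.ndarray          # (k, d) member coordinate sums
    n_dist_evals: int                # point-to-center distance evaluations


def filter_assign(tree: KDTree, centers) -> FilterResult:
    """Assign every point to its nearest center via candidate filtering.

    Traversal starts with all centers as candidates at the root; a candidate
    is pruned for a cell when the cell's winning candidate dominates it over
    the whole bounding box.  A subtree with a single surviving candidate is
    assigned in bulk from its stored count/vector_sum.  Output is identical to
    brute-force nearest-center assignment (ties -> lowest center index).
    """
    from .clustering import CenterSet  # local import to avoid a cycle

    if isinstance(centers, CenterSet):
        centers = centers.centers
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[1] != tree.dim:
        raise ValueError("center dimension does not match tree dimension")
    k = centers.shape[0]
    coords = tree.points.coords
    labels = np.empty(tree.points.n, dtype=np.int64)
    counts = np.zeros(k, dtype=np.int64)
    sums = np.zeros((k, tree.dim))
    evals = 0

    def visit(node: KDNode, cand: np.ndarray) -> None:
        nonlocal evals
        if cand.shape[0] == 1:
            c = int(cand[0])
            labels[tree.subtree_indices(node)] = c
            counts[c] += node.count
            sums[c] += node.vector_sum
            return
        if node.is_leaf:
            idx = tree.subtree_indices(node)
            d2 = cdist(coords[idx], centers[cand], metric="sqeuclidean")
            evals += d2.size
            win = cand[np.argmin(d2, axis=1)]  # cand ascending -> lowest index
            labels[idx] = win
            np.add.at(counts, win, 1)
            np.add.at(sums, win, coords[idx])
            return
        mid = 0.5 * (node.bbox_lo + node.bbox_hi)
        dmid = np.einsum("ij,ij->i", centers[cand] - mid, centers[cand] - mid)
        w = int(cand[int(np.argmin(dmid))])
        keep = [c for c in cand if c == w or not _dominates(node, centers, w, int(c))]
        sub = np.asarray(sorted(int(c) for c in keep), dtype=np.int64)
        visit(node.left, sub)
        visit(node.right, sub)

    visit(tree.root, np.arange(k, dtype=np.int64))
    return FilterResult(labels, counts, sums, evals)


def filter_best2(tree: KDTree, centers: np.ndarray):
    """Per-point nearest and second-nearest center via filtering.

    A candidate is pruned for a cell only when at least two distinct surviving
    candidates dominate it over the whole box, so the surviving set always
    contains each point's best and second-best center.  Requires k >= 2.

    Returns ``(labels, d1, d2, n_dist_evals)`` with Euclidean distances.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    k = centers.shape[0]
    if k < 2:
        raise ValueError("filter_best2 requires at least two centers")
    coords = tree.points.coords
    n = tree.points.n
    labels = np.empty(n, dtype=np.int64)
    d1 = np.empty(n)
    d2 = np.empty(n)
    evals = 0

    def scan(node: KDNode, cand: np.ndarray) -> None:
        nonlocal evals
        idx = tree.subtree_indices(node)
        sq = cdist(coords[idx], centers[cand], metric="sqeuclidean")
        evals += sq.size
        best = np.argmin(sq, axis=1)
        labels[idx] = cand[best]
        d1[idx] = np.sqrt(sq[np.arange(idx.size), best])
        sq[np.arange(idx.size), best] = np.inf
        d2[idx] = np.sqrt(np.min(sq, axis=1))

    def visit(node: KDNode, cand: np.ndarray) -> None:
        if node.is_leaf or cand.shape[0] <= 2:
            scan(node, cand)
            return
        keep = []
        for c in cand:
            ndom = sum(
                1 for a in cand if a != c and _dominates(node, centers, int(a), int(c))
            )
            if ndom < 2:
                keep.append(int(c))
        sub = np.asarray(keep, dtype=np.int64)
        visit(node.left, sub)
        visit(node.right, sub)

    visit(tree.root, np.arange(k, dtype=np.int64))
    return labels, d1, d2, evals
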