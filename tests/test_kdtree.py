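"""k-d tree construction, nearest-neighbor search and lossless filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feskm.kdtree import (
    PointSet,
    build_kdtree,
    filter_assign,
    filter_best2,
    nearest_neighbor,
    prune_candidate,
)

from conftest import brute_assign, brute_nearest


class TestPointSet:
    def test_rejects_non_finite_and_duplicate_ids(self):
        with pytest.raises(ValueError, match="finite"):
            PointSet.from_array([[0.0, np.nan]])
        with pytest.raises(ValueError, match="unique"):
            PointSet(np.zeros((2, 2)), np.array([1, 1]))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            PointSet(np.empty((0, 2)), np.array([]))


class TestBuild:
    def test_hand_traced_square(self):
        """Four corners of a square, leaf_size=1: the tied longest side goes
        to dimension 0, split at the midpoint 1.0, giving four singleton
        leaves."""
        ps = PointSet.from_array([[0, 0], [0, 2], [2, 0], [2, 2]])
        tree = build_kdtree(ps, leaf_size=1)
        root = tree.root
        assert root.split_dim == 0
        assert root.split_val == 1.0
        assert root.count == 4
        assert np.allclose(root.vector_sum, [4.0, 4.0])

        def leaves(node):
            if node.is_leaf:
                return [node]
            return leaves(node.left) + leaves(node.right)

        ls = leaves(root)
        assert len(ls) == 4 and all(leaf.count == 1 for leaf in ls)

    def test_single_point_degenerate(self):
        ps = PointSet.from_array([[5.0, 5.0]])
        tree = build_kdtree(ps, leaf_size=10)
        assert tree.root.is_leaf
        assert tree.root.count == 1
        assert np.array_equal(tree.root.bbox_lo, tree.root.bbox_hi)

    def test_coincident_points_stay_in_one_leaf(self):
        ps = PointSet.from_array(np.ones((7, 3)))
        tree = build_kdtree(ps, leaf_size=2)
        assert tree.root.is_leaf  # cannot separate; oversize leaf allowed

    def test_boundary_points_go_left(self):
        # split of [0,2] at 1.0: the point exactly at 1.0 joins the left child
        ps = PointSet.from_array([[0.0], [1.0], [2.0]])
        tree = build_kdtree(ps, leaf_size=1)
        assert tree.root.split_val == 1.0
        assert tree.root.left.count == 2

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 4), st.integers(1, 12))
    def test_partition_conservation(self, seed, dim, leaf_size):
        """Leaves partition the index set; counts and sums aggregate."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 120))
        coords = rng.normal(size=(n, dim)).round(1)  # rounding forces duplicates
        ps = PointSet.from_array(coords)
        tree = build_kdtree(ps, leaf_size=leaf_size)

        seen = []

        def walk(node):
            assert node.count == node.end - node.start
            if node.is_leaf:
                seen.extend(tree.subtree_indices(node).tolist())
            else:
                assert node.count == node.left.count + node.right.count
                assert np.allclose(
                    node.vector_sum, node.left.vector_sum + node.right.vector_sum
                )
                # each splitting hyperplane separates two nonempty groups
                assert node.left.count >= 1 and node.right.count >= 1
                walk(node.left)
                walk(node.right)

        walk(tree.root)
        assert sorted(seen) == list(range(n))

    def test_500_random_points_partition(self, rng):
        ps = PointSet.from_array(rng.normal(size=(500, 3)))
        tree = build_kdtree(ps, leaf_size=10)

        def leaf_indices(node):
            if node.is_leaf:
                return tree.subtree_indices(node).tolist()
            return leaf_indices(node.left) + leaf_indices(node.right)

        idx = leaf_indices(tree.root)
        assert sorted(idx) == list(range(500))


class TestNearestNeighbor:
    def test_query_at_stored_point(self, rng):
        coords = rng.normal(size=(50, 3))
        tree = build_kdtree(PointSet.from_array(coords), leaf_size=4)
        i, d = nearest_neighbor(tree, coords[17])
        assert i == 17 and d == 0.0

    def test_two_point_hand_case(self):
        tree = build_kdtree(PointSet.from_array([[0, 0], [10, 10]]), leaf_size=1)
        i, d = nearest_neighbor(tree, [1.0, 1.0])
        assert i == 0
        assert d == pytest.approx(np.sqrt(2.0))

    def test_dimension_mismatch(self):
        tree = build_kdtree(PointSet.from_array([[0.0, 0.0]]), leaf_size=1)
        with pytest.raises(ValueError, match="dimension"):
            nearest_neighbor(tree, [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("dim", [1, 2, 5, 16])
    def test_matches_linear_scan(self, dim, rng):
        coords = rng.normal(size=(200, dim)).round(1)  # includes duplicates
        tree = build_kdtree(PointSet.from_array(coords), leaf_size=7)
        for _ in range(50):
            q = rng.normal(size=dim) * 2
            got = nearest_neighbor(tree, q)
            want = brute_nearest(coords, q)
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1], rel=1e-12)


class TestPruneCandidate:
    def test_far_candidate_pruned(self):
        assert prune_candidate([0, 0], [1, 1], candidate=[10, 10], winner=[0.5, 0.5])

    def test_candidate_inside_box_never_pruned(self):
        assert not prune_candidate([0, 0], [1, 1], candidate=[0.5, 0.5], winner=[5, 5])

    def test_invalid_box(self):
        with pytest.raises(ValueError, match="box"):
            prune_candidate([1, 0], [0, 1], [2, 2], [0, 0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_lossless_on_lattice(self, seed):
        """Whenever a candidate is pruned, no point of a 21x21 lattice of the
        box is closer to the candidate than to the winner."""
        rng = np.random.default_rng(seed)
        lo = rng.uniform(-5, 5, size=2)
        hi = lo + rng.uniform(0.1, 5, size=2)
        winner = rng.uniform(-10, 10, size=2)
        cand = rng.uniform(-10, 10, size=2)
        if np.allclose(cand, winner):
            return
        if prune_candidate(lo, hi, cand, winner):
            gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], 21), np.linspace(lo[1], hi[1], 21))
            grid = np.column_stack([gx.ravel(), gy.ravel()])
            dc = ((grid - cand) ** 2).sum(axis=1)
            dw = ((grid - winner) ** 2).sum(axis=1)
            assert not np.any(dc < dw - 1e-12)


class TestFilterAssign:
    def test_all_centers_coincident(self, rng):
        coords = rng.normal(size=(40, 2))
        tree = build_kdtree(PointSet.from_array(coords), leaf_size=5)
        centers = np.tile([[0.3, -0.1]], (4, 1))
        res = filter_assign(tree, centers)
        assert np.all(res.assignments == 0)
        assert res.counts.sum() == 40

    def test_k1_conserves_vector_sum(self, rng):
        coords = rng.normal(size=(60, 3))
        tree = build_kdtree(PointSet.from_array(coords), leaf_size=5)
        res = filter_assign(tree, np.zeros((1, 3)))
        assert np.all(res.assignments == 0)
        assert np.allclose(res.vector_sums[0], coords.sum(axis=0))

    def test_separated_blobs_match_blob_means(self, two_blobs):
        points, truth = two_blobs
        tree = build_kdtree(points, leaf_size=10)
        centers = np.array([[0.0, 0.0], [20.0, 20.0]])
        res = filter_assign(tree, centers)
        assert np.array_equal(res.assignments, truth)
        assert np.array_equal(res.assignments, brute_assign(points.coords, centers))

    @pytest.mark.parametrize("dim", [1, 2, 5, 16])
    def test_matches_brute_force(self, dim, rng):
        """Filtered assignment equals brute force on random instances
        including duplicate points, coincident centers and k larger than the
        number of distinct points."""
        for trial in range(15):
            n = int(rng.integers(5, 150))
            coords = rng.normal(size=(n, dim)).round(1)
            k = int(rng.integers(1, 12))
            if trial % 3 == 0:  # centers drawn from the (duplicated) data
                centers = coords[rng.integers(0, n, size=k)]
            else:
                centers = rng.normal(size=(k, dim))
            if trial % 4 == 0 and k >= 2:
                centers[1] = centers[0]  # coincident centers
            tree = build_kdtree(PointSet.from_array(coords), leaf_size=4)
            res = filter_assign(tree, centers)
            expect = brute_assign(coords, centers)
            assert np.array_equal(res.assignments, expect)
            assert np.array_equal(res.counts, np.bincount(expect, minlength=k))

    def test_counts_and_sums_consistent(self, rng):
        coords = rng.normal(size=(120, 2))
        centers = rng.normal(size=(5, 2))
        tree = build_kdtree(PointSet.from_array(coords), leaf_size=8)
        res = filter_assign(tree, centers)
        for c in range(5):
            members = coords[res.assignments == c]
            assert res.counts[c] == len(members)
            assert np.allclose(res.vector_sums[c], members.sum(axis=0) if len(members) else 0.0)

    def test_distance_eval_count_beats_brute_force(self, rng):
        """On 10,000 planar points with 10 separated centers the filtering
        pass needs far fewer point-center distance evaluations than N*k."""
        centers = np.array([[i * 10.0, (i % 3) * 10.0] for i in range(10)])
        coords = np.vstack([
            rng.normal(c, 1.0, size=(1000, 2)) for c in centers
        ])
        tree = build_kdtree(PointSet.from_array(coords), leaf_size=10)
        res = filter_assign(tree, centers)
        assert res.n_dist_evals < coords.shape[0] * 10
        assert np.array_equal(res.assignments, brute_assign(coords, centers))


class TestFilterBest2:
    def test_best_two_distances_match_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            k = int(rng.integers(2, 9))
            coords = rng.normal(size=(n, 2)) * 3
            centers = rng.normal(size=(k, 2)) * 3
            tree = build_kdtree(PointSet.from_array(coords), leaf_size=6)
            labels, d1, d2, _ = filter_best2(tree, centers)
            full = np.sqrt(((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
            order = np.sort(full, axis=1)
            assert np.array_equal(labels, np.argmin(full, axis=1))
            assert np.allclose(d1, order[:, 0])
            assert np.allclose(d2, order[:, 1])
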