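"""Internal/boundary division, cage-constrained connection, assignment."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

from cdclust.dcm import DCMField, compute_dcm_field
from cdclust.errors import AllBoundaryError, ParameterError
from cdclust.metrics import ari
from cdclust.neighbors import PointSet, build_knn
from cdclust.partition import (
    assign_boundary,
    cdc_cluster,
    connect_internal,
    divide,
    reachable_distances,
)
from cdclust.synthetic import gen_blobs, gen_ring_island


def brute_force_components(coords, reachable):
    """O(m^2) union-find oracle for the pairwise association rule."""
    m = coords.shape[0]
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    d = squareform(pdist(coords))
    for i in range(m):
        for j in range(i + 1, m):
            if d[i, j] <= reachable[i] + reachable[j]:
                parent[find(i)] = find(j)
    roots = {}
    labels = np.empty(m, dtype=int)
    for i in range(m):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots))
    return labels


class TestDivide:
    def test_direct_threshold(self):
        field = DCMField(np.array([0.9, 0.5, 0.1, 0.05]))
        is_boundary, used = divide(field, threshold=0.4)
        assert is_boundary.tolist() == [True, True, False, False]
        assert used == 0.4

    def test_ratio_rank_rule(self, rng):
        values = rng.random(10)
        is_boundary, used = divide(DCMField(values), ratio=0.7)
        # rank = round(10 * 0.3) = 3: threshold is the 3rd-largest DCM
        assert used == np.sort(values)[::-1][2]
        assert is_boundary.sum() >= 3

    def test_extreme_ratio_uses_largest_value(self, rng):
        values = rng.random(100)
        _, used = divide(DCMField(values), ratio=0.99)
        assert used == values.max()

    def test_requires_exactly_one_selector(self):
        field = DCMField(np.array([0.1, 0.9]))
        with pytest.raises(ParameterError):
            divide(field)
        with pytest.raises(ParameterError):
            divide(field, threshold=0.5, ratio=0.9)

    def test_all_boundary_is_an_error(self):
        with pytest.raises(AllBoundaryError):
            divide(DCMField(np.array([0.5, 0.6, 0.7])), threshold=0.1)

    def test_all_internal_warns(self):
        with pytest.warns(UserWarning, match="no boundary"):
            divide(DCMField(np.array([0.1, 0.2])), threshold=0.9)


class TestReachableDistances:
    def test_minimum_over_boundary_set(self):
        pts = PointSet(np.array([[0.0, 0], [3, 0], [0, 4]]))
        r = reachable_distances(pts, np.array([False, True, True]))
        assert r[0] == 3.0
        assert np.isnan(r[1]) and np.isnan(r[2])

    def test_coincident_boundary_gives_zero(self):
        pts = PointSet(np.array([[1.0, 1], [1, 1], [5, 5]]))
        r = reachable_distances(pts, np.array([False, True, True]))
        assert r[0] == 0.0

    def test_brute_force_oracle(self, rng):
        coords = rng.random((300, 2))
        is_boundary = rng.random(300) < 0.3
        is_boundary[0] = False  # keep at least one internal point
        pts = PointSet(coords)
        r = reachable_distances(pts, is_boundary)
        expected = cdist(coords[~is_boundary], coords[is_boundary]).min(axis=1)
        np.testing.assert_allclose(r[~is_boundary], expected)


class TestConnectInternal:
    def test_join_within_reachable_sum(self):
        pts = PointSet(np.array([[0.0, 0], [1.5, 0], [9, 9]]))
        is_boundary = np.array([False, False, True])
        labels = connect_internal(pts, is_boundary, np.array([1.0, 0.6, np.nan]))
        assert labels[0] == labels[1] == 0

    def test_no_direct_join_without_chain(self):
        pts = PointSet(np.array([[0.0, 0], [1.5, 0], [9, 9]]))
        is_boundary = np.array([False, False, True])
        labels = connect_internal(pts, is_boundary, np.array([0.5, 0.6, np.nan]))
        assert labels[0] != labels[1]

    def test_chain_transitivity(self):
        pts = PointSet(np.array([[0.0, 0], [1.0, 0], [2.0, 0], [9, 9]]))
        is_boundary = np.array([False, False, False, True])
        r = np.array([0.55, 0.55, 0.55, np.nan])
        labels = connect_internal(pts, is_boundary, r)
        assert labels[0] == labels[1] == labels[2]

    def test_brute_force_union_find_oracle(self, rng):
        coords = rng.random((150, 2)) * 3
        is_boundary = np.zeros(150, dtype=bool)
        r = np.full(150, np.nan)
        r[:] = rng.random(150) * 0.3
        labels = connect_internal(PointSet(coords), is_boundary, r)
        oracle = brute_force_components(coords, r)
        # same partitions up to label naming
        assert ari(oracle, labels) == 1.0
        # and the smallest-member-index naming convention
        first_seen = {}
        for lab in labels:
            first_seen.setdefault(lab, len(first_seen))
        assert all(lab == first_seen[lab] for lab in labels)


class TestAssignBoundary:
    def test_nearest_internal_wins(self):
        pts = PointSet(np.array([[0.0, 0], [1, 0], [3, 0]]))
        is_boundary = np.array([True, False, False])
        labels = np.array([-1, 0, 1])
        out = assign_boundary(pts, is_boundary, labels)
        assert out[0] == 0

    def test_distance_tie_takes_smaller_index(self):
        pts = PointSet(np.array([[0.0, 0], [-1, 0], [1, 0]]))
        is_boundary = np.array([True, False, False])
        out = assign_boundary(pts, is_boundary, np.array([-1, 0, 1]))
        assert out[0] == 0

    def test_no_boundary_is_noop(self):
        pts = PointSet(np.array([[0.0, 0], [1, 0]]))
        labels = np.array([0, 0])
        out = assign_boundary(pts, np.array([False, False]), labels)
        assert np.array_equal(out, labels)


def label_sets(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


class TestCdcCluster:
    def test_recovers_two_distant_blobs(self):
        ds = gen_blobs(400, [[0, 0], [10, 0]], 1.0, seed=3)
        part = cdc_cluster(ds.coords, k=10, ratio=0.9)
        assert part.n_clusters == 2
        assert ari(ds.labels, part.labels) == 1.0
        assert part.m + part.is_boundary.sum() == 400

    def test_ring_island_regime(self):
        ds = gen_ring_island(600, 200, radius=5.0, width=0.3, core_sigma=0.4, seed=9)
        part = cdc_cluster(ds.coords, k=20, ratio=0.85)
        assert part.n_clusters == 2
        assert ari(ds.labels, part.labels) >= 0.95

    def test_all_internal_gives_single_cluster(self):
        ds = gen_blobs(200, [[0, 0]], 1.0, seed=4)
        with pytest.warns(UserWarning):
            part = cdc_cluster(ds.coords, k=10, threshold=1.1)
        assert part.n_clusters == 1
        assert np.all(part.labels == 0)

    def test_labels_complete_and_contiguous(self):
        ds = gen_blobs(300, [[0, 0], [8, 0], [0, 8]], 0.7, seed=5)
        part = cdc_cluster(ds.coords, k=10, ratio=0.9)
        assert part.labels.shape == (300,)
        assert set(part.labels) == set(range(part.n_clusters))

    def test_permutation_invariance(self, rng):
        ds = gen_blobs(300, [[0, 0], [9, 0]], [0.6, 1.0], seed=6)
        part = cdc_cluster(ds.coords, k=12, ratio=0.9)
        perm = rng.permutation(300)
        part_p = cdc_cluster(ds.coords[perm], k=12, ratio=0.9)
        relabeled = np.empty(300, dtype=int)
        relabeled[perm] = part_p.labels
        assert label_sets(part.labels) == label_sets(relabeled)

    def test_rescaling_invariance(self):
        ds = gen_blobs(300, [[0, 0], [9, 0]], [0.6, 1.0], seed=6)
        a = cdc_cluster(ds.coords, k=12, ratio=0.9)
        b = cdc_cluster(ds.coords * 7.3, k=12, ratio=0.9)
        assert label_sets(a.labels) == label_sets(b.labels)

    def test_cage_blocks_cross_blob_connections(self):
        # mark each blob's convex hull as boundary: no internal point of
        # one blob may then join an internal point of the other
        from scipy.spatial import ConvexHull

        ds = gen_blobs(200, [[0, 0], [6, 0]], 0.8, seed=7)
        coords = ds.coords
        is_boundary = np.zeros(200, dtype=bool)
        for lab in (0, 1):
            idx = np.flatnonzero(ds.labels == lab)
            is_boundary[idx[ConvexHull(coords[idx]).vertices]] = True
        pts = PointSet(coords)
        r = reachable_distances(pts, is_boundary)
        labels = connect_internal(pts, is_boundary, r)
        internal = ~is_boundary
        assert len({(lab, true) for lab, true in
                    zip(labels[internal], ds.labels[internal])}) == 2
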