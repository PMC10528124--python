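"""Adjacency operators and the two clustering traversals.

Brute-force oracles: Moore adjacency via Chebyshev distance 1 over all
stored cells; connected components via union-find; k-adjacency via an
all-pairs distance scan.
"""

import itertools

import numpy as np
import pytest

from cags import (
    CAGSConfig,
    PointSet,
    adjacency_offsets,
    adjacent_existing_cells,
    assign_peripheral_cells,
    build_grid,
    cluster_core_cells,
    cluster_high_dimensional,
    halo_threshold,
    k_adjacent_cells,
    merge_small_clusters,
    run_cags,
    split_core_peripheral,
)
from cags.cluster import _rank_cells


# ---------------------------------------------------------------- oracles

def chebyshev_neighbors(grid, num):
    """All stored cells at Chebyshev distance exactly 1."""
    loc = np.array(grid.cells[num].location)
    out = []
    for other, cell in grid.cells.items():
        if other == num:
            continue
        if np.abs(np.array(cell.location) - loc).max() == 1:
            out.append(other)
    return sorted(out)


def union_find_components(grid, members):
    """Connected components of `members` under Moore adjacency."""
    parent = {n: n for n in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    member_set = set(members)
    for n in members:
        for nb in chebyshev_neighbors(grid, n):
            if nb in member_set:
                parent[find(n)] = find(nb)
    comps = {}
    for n in members:
        comps.setdefault(find(n), set()).add(n)
    return [frozenset(c) for c in comps.values()]


def grid_at_cells(locations, R=None, densities=None):
    """Construct a GridSpace whose occupied cells sit exactly at the given
    integer locations (unit cells over [0, R]^d), with points jittered
    around each cell centre."""
    from cags import CoordinateSequences, GridCell, GridSpace, location_to_cell_number

    locations = [tuple(l) for l in locations]
    d = len(locations[0])
    R = R or max(max(l) for l in locations)
    densities = densities or [1] * len(locations)
    rng = np.random.default_rng(0)
    pts, cells = [], {}
    for loc, dens in zip(locations, densities):
        centre = np.array(loc, dtype=float) - 0.5
        members = np.arange(len(pts), len(pts) + dens)
        for _ in range(dens):
            pts.append(centre + rng.uniform(-0.25, 0.25, size=d))
        num = location_to_cell_number(loc, R, d)
        cells[num] = GridCell(num, loc, members)
    seq = CoordinateSequences(
        np.tile(np.arange(R + 1, dtype=float), (d, 1)), R)
    ps = PointSet(np.array(pts))
    return ps, GridSpace(d, R, seq, cells)


# ---------------------------------------------------------------- offsets

class TestAdjacencyOffsets:
    @pytest.mark.parametrize("d", [1, 2, 3, 4])
    def test_cardinality_and_negation_closure(self, d):
        offs = adjacency_offsets(d)
        assert len(offs) == 3**d - 1
        as_set = {tuple(o) for o in offs}
        assert len(as_set) == 3**d - 1
        assert {tuple(-o) for o in offs} == as_set

    def test_d1_and_d2_enumeration(self):
        assert {tuple(o) for o in adjacency_offsets(1)} == {(-1,), (1,)}
        expected = {(-1, 1), (-1, 0), (-1, -1), (0, -1),
                    (0, 1), (1, -1), (1, 0), (1, 1)}
        assert {tuple(o) for o in adjacency_offsets(2)} == expected


class TestAdjacentExistingCells:
    def test_lone_cell(self):
        _, grid = grid_at_cells([(2, 2)], R=4)
        offs = adjacency_offsets(2)
        cell = next(iter(grid.cells.values()))
        assert adjacent_existing_cells(cell, grid, offs) == []

    def test_corner_cell_in_full_grid(self):
        locs = list(itertools.product(range(1, 5), repeat=2))
        _, grid = grid_at_cells(locs, R=4)
        assert grid.n_cells == 16
        offs = adjacency_offsets(2)
        corner = grid.cell_at((1, 1))
        assert len(adjacent_existing_cells(corner, grid, offs)) == 3

    def test_matches_brute_force_on_random_sparse_grids(self, rng):
        offs = adjacency_offsets(2)
        for _ in range(10):
            ps = PointSet(rng.normal(size=(80, 2)))
            grid = build_grid(ps, 1.5)
            for num, cell in grid.cells.items():
                got = sorted(c.cell_number
                             for c in adjacent_existing_cells(cell, grid, offs))
                assert got == chebyshev_neighbors(grid, num)


# ------------------------------------------------------------- stage 1/2

def full_core_partition(grid):
    return split_core_peripheral(grid, 0.0)


class TestCoreTraversal:
    def test_single_core_cell(self):
        _, grid = grid_at_cells([(2, 2)], R=3)
        labels, centers = cluster_core_cells(grid, full_core_partition(grid))
        assert set(labels.values()) == {1}
        assert len(centers) == 1

    def test_blocks_and_l_shape(self):
        # two 2-cell blocks separated by >= 2 empty columns -> two clusters
        _, grid = grid_at_cells([(1, 1), (2, 1), (5, 1), (6, 1)], R=6)
        labels, centers = cluster_core_cells(grid, full_core_partition(grid))
        assert len(centers) == 2
        # L-shaped connected block -> one cluster
        _, grid = grid_at_cells([(1, 1), (1, 2), (2, 2)], R=4)
        labels, centers = cluster_core_cells(grid, full_core_partition(grid))
        assert len(centers) == 1

    def test_densest_block_gets_label_one(self):
        _, grid = grid_at_cells([(1, 1), (5, 5)], R=6, densities=[2, 7])
        labels, centers = cluster_core_cells(grid, full_core_partition(grid))
        dense = grid.cell_at((5, 5)).cell_number
        assert labels[dense] == 1
        assert centers[0] == dense

    def test_equals_brute_force_components(self, rng):
        for trial in range(25):
            ps = PointSet(rng.normal(size=(120, 2)))
            grid = build_grid(ps, 1.5)
            part = split_core_peripheral(grid, halo_threshold(grid, 0.8))
            labels, _ = cluster_core_cells(grid, part)
            got = {}
            for num, lab in labels.items():
                got.setdefault(lab, set()).add(num)
            assert {frozenset(s) for s in got.values()} == \
                set(union_find_components(grid, sorted(part.core_cells)))


class TestPeripheralAssignment:
    def test_no_peripheral_cells_is_noop(self):
        _, grid = grid_at_cells([(1, 1), (2, 2)], R=3)
        part = full_core_partition(grid)
        labels, centers = cluster_core_cells(grid, part)
        ps = PointSet(np.array([[0.5, 0.5], [1.5, 1.5], [0.0, 0.0], [3.0, 3.0]]))
        out, cent = assign_peripheral_cells(grid, part, labels, centers, ps)
        assert out == labels and cent == centers

    def test_joins_nearer_cluster_by_centre_distance(self):
        # peripheral cell at (3,1) between cores at (1,1) and (5,1);
        # its centre is closer to the (5,1) core's centre
        ps, grid = grid_at_cells([(1, 1), (4, 1), (5, 1)], R=5,
                                 densities=[5, 1, 5])
        thr = 3.0
        part = split_core_peripheral(grid, thr)
        assert grid.cell_at((4, 1)).cell_number in part.peripheral_cells
        labels, centers = cluster_core_cells(grid, part)
        out, _ = assign_peripheral_cells(grid, part, labels, centers, ps)
        near_core = labels[grid.cell_at((5, 1)).cell_number]
        assert out[grid.cell_at((4, 1)).cell_number] == near_core

    def test_isolated_peripheral_becomes_new_cluster(self):
        ps, grid = grid_at_cells([(1, 1), (5, 5)], R=5, densities=[5, 1])
        part = split_core_peripheral(grid, 3.0)
        labels, centers = cluster_core_cells(grid, part)
        out, cent = assign_peripheral_cells(grid, part, labels, centers, ps)
        lone = grid.cell_at((5, 5)).cell_number
        assert out[lone] == 2
        assert len(cent) == 2

    def test_chain_attaches_over_multiple_sweeps(self):
        # core at (1,1); peripherals at (2,1) and (3,1): the far one can only
        # attach after the near one is labeled
        ps, grid = grid_at_cells([(1, 1), (2, 1), (3, 1)], R=4,
                                 densities=[6, 1, 1])
        part = split_core_peripheral(grid, 3.0)
        labels, centers = cluster_core_cells(grid, part)
        out, cent = assign_peripheral_cells(grid, part, labels, centers, ps)
        assert set(out.values()) == {1}
        assert len(cent) == 1


# ---------------------------------------------------------- k-adjacency

class TestKAdjacency:
    def test_strict_inequality_k1_no_neighbors(self):
        _, grid = grid_at_cells([(1, 1), (2, 1)], R=3)
        cell = grid.cell_at((1, 1))
        assert k_adjacent_cells(grid, cell, 1.0) == []

    def test_k2_von_neumann_semantics(self):
        _, grid = grid_at_cells([(2, 2), (3, 2), (3, 3)], R=4)
        cell = grid.cell_at((2, 2))
        got = {c.location for c in k_adjacent_cells(grid, cell, 2.0)}
        assert got == {(3, 2)}      # squared distance 1 < 2; diagonal is 2

    def test_matches_brute_force_scan(self, rng):
        for _ in range(10):
            ps = PointSet(rng.normal(size=(100, 3)))
            grid = build_grid(ps, 1.2)
            for num, cell in grid.cells.items():
                got = sorted(c.cell_number
                             for c in k_adjacent_cells(grid, cell, 2.0))
                loc = np.array(cell.location)
                expect = sorted(
                    other for other, c in grid.cells.items()
                    if other != num
                    and ((np.array(c.location) - loc) ** 2).sum() < 2)
                assert got == expect


class TestHighDimensionalPass:
    def test_single_cell(self):
        _, grid = grid_at_cells([(2, 2)], R=3)
        labels, centers = cluster_high_dimensional(grid, 2.0)
        assert set(labels.values()) == {1}

    def test_star_absorbed_in_one_cluster(self):
        locs = [(3, 3), (2, 3), (4, 3), (3, 2), (3, 4)]
        _, grid = grid_at_cells(locs, R=5, densities=[9, 1, 1, 1, 1])
        labels, centers = cluster_high_dimensional(grid, 2.0)
        assert set(labels.values()) == {1}
        assert len(centers) == 1

    def test_chain_is_single_hop_not_transitive(self):
        # c1 densest; c1 absorbs c2 but not c3, which seeds cluster 2
        locs = [(1, 1), (2, 1), (3, 1)]
        _, grid = grid_at_cells(locs, R=4, densities=[5, 2, 1])
        labels, centers = cluster_high_dimensional(grid, 2.0)
        c = {grid.cell_at(l).cell_number: l for l in locs}
        by_loc = {loc: labels[n] for n, loc in c.items()}
        assert by_loc[(1, 1)] == 1 and by_loc[(2, 1)] == 1
        assert by_loc[(3, 1)] == 2

    def test_transitive_variant_closes_the_chain(self):
        locs = [(1, 1), (2, 1), (3, 1)]
        _, grid = grid_at_cells(locs, R=4, densities=[5, 2, 1])
        labels, _ = cluster_high_dimensional(grid, 2.0, expansion="transitive")
        assert set(labels.values()) == {1}


# -------------------------------------------------------------- merging

class TestMerging:
    def _result(self):
        ps, grid = grid_at_cells(
            [(1, 1), (1, 2), (2, 1), (2, 2), (5, 5)], R=5,
            densities=[3, 3, 3, 3, 1])
        labels, centers = cluster_core_cells(grid, full_core_partition(grid))
        return ps, grid, labels, centers

    def test_zero_coefficient_noop(self):
        ps, grid, labels, centers = self._result()
        out, cent = merge_small_clusters(labels, centers, grid, ps, 0.0)
        assert out == labels and cent == centers

    def test_small_cluster_dissolved(self):
        ps, grid, labels, centers = self._result()
        # scales {4, 1}; f_M = 0.5 -> threM = 1.5 -> the 1-cell cluster merges
        out, cent = merge_small_clusters(labels, centers, grid, ps, 0.5)
        assert len(cent) == 1
        assert set(out.values()) == {1}

    def test_equal_scales_no_merge(self):
        ps, grid = grid_at_cells([(1, 1), (5, 5)], R=5, densities=[2, 2])
        labels, centers = cluster_core_cells(grid, full_core_partition(grid))
        out, cent = merge_small_clusters(labels, centers, grid, ps, 0.9)
        assert len(cent) == 2


# ------------------------------------------------------------- pipeline

class TestRunCags:
    def test_two_blob_recovery(self, two_blobs):
        result = run_cags(two_blobs, CAGSConfig(resolution_coefficient=1.0))
        assert result.n_clusters == 2
        # labels match generation up to permutation
        a = result.point_labels[:100]
        b = result.point_labels[100:]
        assert len(set(a)) == 1 and len(set(b)) == 1 and a[0] != b[0]

    def test_two_blob_recovery_across_seeds(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            pts = np.vstack([r.normal((0, 0), 0.5, size=(100, 2)),
                             r.normal((10, 10), 0.5, size=(100, 2))])
            # f_M dissolves the occasional stray single-cell cluster an
            # extreme outlier can form
            res = run_cags(PointSet(pts), CAGSConfig(resolution_coefficient=1.0,
                                                     merger_coefficient=0.2))
            hits += res.n_clusters == 2
        assert hits == 20

    def test_single_point(self):
        res = run_cags(PointSet(np.array([[3.0, 4.0]])))
        assert res.n_clusters == 1
        assert list(res.point_labels) == [1]

    def test_all_noise_zero_clusters(self, rng):
        # scattered singletons with a high noise coefficient
        ps = PointSet(rng.uniform(0, 100, size=(30, 2)))
        res = run_cags(ps, CAGSConfig(resolution_coefficient=3.0,
                                      noise_coefficient=1.5))
        if res.n_clusters == 0:
            assert np.all(res.point_labels == 0)

    def test_determinism(self, two_blobs):
        cfg = CAGSConfig(resolution_coefficient=1.0, halo_coefficient=0.5)
        a = run_cags(two_blobs, cfg)
        b = run_cags(two_blobs, cfg)
        assert np.array_equal(a.point_labels, b.point_labels)

    def test_permutation_invariance_up_to_relabeling(self, two_blobs, rng):
        cfg = CAGSConfig(resolution_coefficient=1.0, halo_coefficient=0.5)
        perm = rng.permutation(two_blobs.n_points)
        shuffled = PointSet(two_blobs.points[perm])
        a = run_cags(two_blobs, cfg).point_labels
        b = run_cags(shuffled, cfg).point_labels
        restored = np.empty_like(b)
        restored[perm] = b
        mapping = {}
        for x, y in zip(a, restored):
            assert mapping.setdefault(x, y) == y

    def test_affine_invariance_of_labels(self, two_blobs):
        cfg = CAGSConfig(resolution_coefficient=1.0, halo_coefficient=0.8)
        a = run_cags(two_blobs, cfg).point_labels
        scaled = PointSet(two_blobs.points * np.array([3.0, 0.2]) + 7.0)
        b = run_cags(scaled, cfg).point_labels
        assert np.array_equal(a, b)

    def test_noise_points_labeled_zero(self):
        r = np.random.default_rng(3)
        blob = r.normal((0, 0), 0.5, size=(200, 2))
        lone = np.array([[30.0, 30.0]])
        ps = PointSet(np.vstack([blob, lone]))
        res = run_cags(ps, CAGSConfig(resolution_coefficient=1.0,
                                      noise_coefficient=0.5))
        assert res.point_labels[-1] == 0
        assert res.n_clusters >= 1

    def test_cluster_count_matches_labels(self, rng):
        ps = PointSet(rng.normal(size=(300, 2)))
        res = run_cags(ps, CAGSConfig(resolution_coefficient=1.5,
                                      noise_coefficient=0.5,
                                      halo_coefficient=0.5))
        nonzero = set(res.point_labels) - {0}
        assert nonzero == set(range(1, res.n_clusters + 1))

    def test_rank_ties_broken_by_cell_number(self):
        _, grid = grid_at_cells([(1, 1), (3, 3)], R=3)
        nums = _rank_cells(grid, grid.cells)
        assert nums == sorted(grid.cells)
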