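"""Cluster recognition by adjacent-grid searching.

Two traversal strategies operate on the sparse grid:

* low-dimensional (d below the cutoff): two-stage expansion — core cells are
  grouped into maximal Moore-connected components seeded densest-first, then
  peripheral (halo) cells are attached, sweep by sweep, to the nearest
  already-labeled adjacent cell (distance between cell centres in data
  space);
* high-dimensional: the Moore stencil (3**d - 1 offsets) is no longer
  practical, so each cell ranked by descending density seeds a cluster and
  absorbs its still-unlabeled k-adjacent cells in a single pass.

The k-adjacency metric is configurable because the distance underlying the
threshold ``k`` admits several readings; the default is the squared
Euclidean distance between integer location vectors with strict ``< k``,
which at the default ``k = 2`` reduces to von-Neumann adjacency.  A
transitive-expansion variant of the high-dimensional pass is available for
calibration.

Everything is deterministic: density ties are broken by ascending cell
number, nearest-cell ties by lowest cluster id.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .grid import (
    GridCell,
    GridSpace,
    PointSet,
    build_grid,
    cell_center,
)
from .partition import (
    CellPartition,
    PartitionThresholds,
    halo_threshold,
    noise_threshold,
    remesh,
    split_core_peripheral,
    split_noise,
)

logger = logging.getLogger("cags")

ADJACENCY_METRICS = ("squared-location", "euclidean-location", "euclidean-center")
EXPANSIONS = ("single-hop", "transitive")

__all__ = [
    "CAGSConfig",
    "ClusterResult",
    "adjacency_offsets",
    "adjacent_existing_cells",
    "cluster_core_cells",
    "assign_peripheral_cells",
    "k_adjacent_cells",
    "cluster_high_dimensional",
    "merge_small_clusters",
    "run_cags",
]


@dataclass(frozen=True)
class CAGSConfig:
    """Pipeline coefficients.

    f_R scales the grid resolution, f_N the noise threshold, f_H the halo
    threshold, f_M the small-cluster merge threshold; k is the adjacency
    distance threshold of the high-dimensional pass (default 2), applied for
    d >= high_dim_cutoff axes.
    """

    resolution_coefficient: float = 1.0
    noise_coefficient: float = 0.0
    halo_coefficient: float = 0.0
    merger_coefficient: float = 0.0
    adjacency_threshold: float = 2.0
    high_dim_cutoff: int = 5
    adjacency_metric: str = "squared-location"
    expansion: str = "single-hop"

    def __post_init__(self) -> None:
        for name in ("resolution_coefficient",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_coefficient", "halo_coefficient", "merger_coefficient"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.adjacency_threshold <= 0:
            raise ValueError("adjacency_threshold must be > 0")
        if self.high_dim_cutoff < 2:
            raise ValueError("high_dim_cutoff must be >= 2")
        if self.adjacency_metric not in ADJACENCY_METRICS:
            raise ValueError(f"adjacency_metric must be one of {ADJACENCY_METRICS}")
        if self.expansion not in EXPANSIONS:
            raise ValueError(f"expansion must be one of {EXPANSIONS}")


@dataclass
class ClusterResult:
    """Outcome of a clustering run.

    Point labels are 1..m for clustered points and 0 for noise.  Per-cluster
    summaries are indexed by ``label - 1``.
    """

    point_labels: np.ndarray
    cell_labels: Dict[int, int]
    n_clusters: int
    center_cells: List[int]            # densest cell of each cluster
    mean_cell_density: np.ndarray      # mean member count of the cluster's cells
    cluster_scale: np.ndarray          # number of cells per cluster
    grid: Optional[GridSpace] = None   # the (re-meshed) grid the labels live on
    noise_cells: frozenset = field(default_factory=frozenset)
    partition: Optional[CellPartition] = None


def adjacency_offsets(n_dims: int) -> np.ndarray:
    """All ``3**d - 1`` nonzero offset vectors in {-1, 0, 1}**d."""
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    offs = np.array(list(itertools.product((-1, 0, 1), repeat=n_dims)), dtype=np.int64)
    return offs[np.any(offs != 0, axis=1)]


def adjacent_existing_cells(cell: GridCell, grid: GridSpace,
                            offsets: np.ndarray) -> List[GridCell]:
    """Nonnull cells at Moore-neighbor locations of ``cell``; locations
    falling outside 1..R are skipped implicitly (never stored)."""
    loc = np.asarray(cell.location)
    found = []
    for off in offsets:
        neighbor = grid.cell_at(loc + off)
        if neighbor is not None:
            found.append(neighbor)
    return found


def _rank_cells(grid: GridSpace, cell_numbers) -> List[int]:
    """Descending density, ties by ascending cell number."""
    return sorted(cell_numbers, key=lambda n: (-grid.cells[n].density, n))


def cluster_core_cells(grid: GridSpace, partition: CellPartition
                       ) -> Tuple[Dict[int, int], List[int]]:
    """Stage 1: maximal Moore-connected components of the core cells.

    The densest unlabeled core cell seeds each cluster and is recorded as
    its center.  Returns (cell labels, center cell per cluster).
    """
    offsets = adjacency_offsets(grid.dimension)
    labels: Dict[int, int] = {}
    centers: List[int] = []
    core = partition.core_cells
    for seed in _rank_cells(grid, core):
        if seed in labels:
            continue
        m = len(centers) + 1
        centers.append(seed)
        queue = [seed]
        labels[seed] = m
        while queue:
            current = queue.pop()
            for nb in adjacent_existing_cells(grid.cells[current], grid, offsets):
                if nb.cell_number in core and nb.cell_number not in labels:
                    labels[nb.cell_number] = m
                    queue.append(nb.cell_number)
    return labels, centers


def assign_peripheral_cells(grid: GridSpace, partition: CellPartition,
                            labels: Dict[int, int], centers: List[int],
                            points: PointSet) -> Tuple[Dict[int, int], List[int]]:
    """Stage 2: attach peripheral cells to the nearest labeled adjacent cell.

    Distances are between cell centres in data space.  Sweeps repeat so a
    peripheral cell may attach to a peripheral neighbor labeled in an
    earlier sweep; assignments within a sweep use the labels as of the sweep
    start, which makes the result independent of traversal order.  A
    peripheral cell with no nonnull adjacent cells becomes a new cluster,
    and if a sweep stalls the densest remaining cell seeds a new cluster.
    """
    offsets = adjacency_offsets(grid.dimension)
    labels = dict(labels)
    centers = list(centers)
    center_cache: Dict[int, np.ndarray] = {}

    def centre(num: int) -> np.ndarray:
        if num not in center_cache:
            center_cache[num] = cell_center(grid.cells[num], points)
        return center_cache[num]

    unhandled = set(partition.peripheral_cells) - labels.keys()
    while unhandled:
        snapshot = dict(labels)
        assigned: Dict[int, int] = {}
        for pc in _rank_cells(grid, unhandled):
            adj = adjacent_existing_cells(grid.cells[pc], grid, offsets)
            if not adj:
                centers.append(pc)
                labels[pc] = len(centers)        # isolated: new cluster, visible
                assigned[pc] = labels[pc]        # to later sweeps only
                continue
            labeled = [a for a in adj if a.cell_number in snapshot]
            if not labeled:
                continue
            ref = centre(pc)
            best = min(
                labeled,
                key=lambda a: (float(np.linalg.norm(centre(a.cell_number) - ref)),
                               snapshot[a.cell_number]),
            )
            assigned[pc] = snapshot[best.cell_number]
        if assigned:
            labels.update(assigned)
            unhandled -= assigned.keys()
        else:
            seed = _rank_cells(grid, unhandled)[0]
            centers.append(seed)
            labels[seed] = len(centers)
            unhandled.discard(seed)
    return labels, centers


def _cell_coords(grid: GridSpace, cell_numbers: Sequence[int], metric: str,
                 points: Optional[PointSet]) -> np.ndarray:
    if metric in ("squared-location", "euclidean-location"):
        return np.array([grid.cells[n].location for n in cell_numbers], dtype=float)
    if points is None:
        raise ValueError("euclidean-center metric requires the point set")
    return np.array([cell_center(grid.cells[n], points) for n in cell_numbers])


def _k_radius(k: float, metric: str) -> float:
    return float(np.sqrt(k)) if metric == "squared-location" else float(k)


def k_adjacent_cells(grid: GridSpace, cell: GridCell, k: float,
                     metric: str = "squared-location",
                     points: Optional[PointSet] = None) -> List[GridCell]:
    """Cells strictly within distance threshold ``k`` of ``cell`` (excluding
    itself) under the configured metric."""
    nums = list(grid.cells)
    coords = _cell_coords(grid, nums, metric, points)
    ref = _cell_coords(grid, [cell.cell_number], metric, points)[0]
    d2 = ((coords - ref) ** 2).sum(axis=1)
    thr = k if metric == "squared-location" else k * k
    hits = [grid.cells[n] for n, dd in zip(nums, d2)
            if dd < thr and n != cell.cell_number]
    return hits


def cluster_high_dimensional(grid: GridSpace, k: float,
                             metric: str = "squared-location",
                             expansion: str = "single-hop",
                             points: Optional[PointSet] = None
                             ) -> Tuple[Dict[int, int], List[int]]:
    """Single-pass clustering by k-adjacent cell searching.

    Cells ranked by descending density; each still-unlabeled cell seeds a
    cluster and absorbs its still-unlabeled k-adjacent cells.  ``expansion=
    'transitive'`` follows adjacency to closure instead of a single hop.
    """
    nums = _rank_cells(grid, grid.cells)
    coords = _cell_coords(grid, nums, metric, points)
    index = {n: i for i, n in enumerate(nums)}
    tree = cKDTree(coords)
    radius = _k_radius(k, metric)
    pairs = tree.query_pairs(r=radius * (1 + 1e-9), output_type="ndarray")
    neighbors: List[List[int]] = [[] for _ in nums]
    thr = k if metric == "squared-location" else k * k
    for a, b in pairs:
        if ((coords[a] - coords[b]) ** 2).sum() < thr:
            neighbors[a].append(b)
            neighbors[b].append(a)
    labels: Dict[int, int] = {}
    centers: List[int] = []
    for i, num in enumerate(nums):
        if num in labels:
            continue
        m = len(centers) + 1
        centers.append(num)
        labels[num] = m
        if expansion == "single-hop":
            for j in neighbors[i]:
                if nums[j] not in labels:
                    labels[nums[j]] = m
        else:
            queue = [i]
            while queue:
                cur = queue.pop()
                for j in neighbors[cur]:
                    if nums[j] not in labels:
                        labels[nums[j]] = m
                        queue.append(j)
    return labels, centers


def _cluster_scales(labels: Dict[int, int], m: int) -> np.ndarray:
    scale = np.zeros(m, dtype=int)
    for lab in labels.values():
        scale[lab - 1] += 1
    return scale


def merge_small_clusters(labels: Dict[int, int], centers: List[int],
                         grid: GridSpace, points: PointSet,
                         merger_coefficient: float
                         ) -> Tuple[Dict[int, int], List[int]]:
    """Dissolve clusters whose cell count falls below
    ``f_M * (scale_max - scale_min)``; their cells join the surviving
    cluster with the nearest center cell in data space.  f_M = 0 is a no-op;
    if every cluster is below threshold the largest survives."""
    m = len(centers)
    if merger_coefficient == 0 or m <= 1:
        return labels, centers
    scale = _cluster_scales(labels, m)
    thr = merger_coefficient * (scale.max() - scale.min())
    survivors = [c + 1 for c in range(m) if scale[c] >= thr]
    if not survivors:
        big = int(np.argmax(scale)) + 1
        survivors = [big]
    if len(survivors) == m:
        return labels, centers
    surv_centers = np.array([cell_center(grid.cells[centers[s - 1]], points)
                             for s in survivors])
    remap = {}
    for old in range(1, m + 1):
        if old in survivors:
            remap[old] = survivors.index(old) + 1
        else:
            ref = cell_center(grid.cells[centers[old - 1]], points)
            dist = np.linalg.norm(surv_centers - ref, axis=1)
            remap[old] = int(np.argmin(dist)) + 1  # argmin takes lowest id on ties
    new_labels = {num: remap[lab] for num, lab in labels.items()}
    new_centers = [centers[s - 1] for s in survivors]
    return new_labels, new_centers


def _finalize(points: PointSet, grid: Optional[GridSpace],
              labels: Dict[int, int], centers: List[int],
              keep_rows: Optional[np.ndarray],
              noise_cells: frozenset,
              partition: Optional[CellPartition]) -> ClusterResult:
    n = points.n_points
    point_labels = np.zeros(n, dtype=int)
    m = len(centers)
    if grid is not None:
        for num, cell in grid.cells.items():
            lab = labels[num]
            rows = cell.members if keep_rows is None else keep_rows[cell.members]
            point_labels[rows] = lab
    mean_density = np.zeros(m)
    scale = _cluster_scales(labels, m) if m else np.zeros(0, dtype=int)
    if m:
        sums = np.zeros(m)
        for num, lab in labels.items():
            sums[lab - 1] += grid.cells[num].density
        mean_density = sums / np.maximum(scale, 1)
    return ClusterResult(
        point_labels=point_labels,
        cell_labels=labels,
        n_clusters=m,
        center_cells=centers,
        mean_cell_density=mean_density,
        cluster_scale=scale,
        grid=grid,
        noise_cells=noise_cells,
        partition=partition,
    )


def run_cags(points: PointSet, config: CAGSConfig = CAGSConfig()) -> ClusterResult:
    """Full pipeline: mesh -> denoise -> re-mesh -> cluster -> merge -> label.

    Deterministic given inputs; noise points get label 0.
    """
    grid0 = build_grid(points, config.resolution_coefficient)
    logger.info("meshed %d points into %d cells (R=%d, d=%d)",
                points.n_points, grid0.n_cells, grid0.resolution, grid0.dimension)
    thre_n = noise_threshold(grid0, config.noise_coefficient)
    noise_cells, retained = split_noise(grid0, thre_n, points)
    if retained is None:
        logger.info("all %d points classified as noise", points.n_points)
        return _finalize(points, None, {}, [], None, noise_cells, None)
    if retained.n_points != points.n_points:
        # retained rows in ascending original order (subset order)
        mask = np.zeros(points.n_points, dtype=bool)
        for num, c in grid0.cells.items():
            if num not in noise_cells:
                mask[c.members] = True
        keep_rows = np.flatnonzero(mask)
    else:
        keep_rows = None
    grid = remesh(retained, config.resolution_coefficient)
    logger.info("re-meshed %d retained points into %d cells (R=%d)",
                retained.n_points, grid.n_cells, grid.resolution)

    if points.n_dims < config.high_dim_cutoff:
        thre_h = halo_threshold(grid, config.halo_coefficient)
        thresholds = PartitionThresholds(thre_n, thre_h,
                                         config.noise_coefficient,
                                         config.halo_coefficient)
        partition = split_core_peripheral(grid, thre_h, thresholds)
        labels, centers = cluster_core_cells(grid, partition)
        labels, centers = assign_peripheral_cells(grid, partition, labels,
                                                  centers, retained)
    else:
        if config.halo_coefficient != 0:
            logger.warning("halo coefficient ignored for d >= %d (k-adjacent path)",
                           config.high_dim_cutoff)
        partition = None
        labels, centers = cluster_high_dimensional(
            grid, config.adjacency_threshold, config.adjacency_metric,
            config.expansion, retained)
    labels, centers = merge_small_clusters(labels, centers, grid, retained,
                                           config.merger_coefficient)
    result = _finalize(points, grid, labels, centers, keep_rows,
                       noise_cells, partition)
    logger.info("found %d clusters (%d noise points)",
                result.n_clusters, int((result.point_labels == 0).sum()))
    return result
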