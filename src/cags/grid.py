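"""Adaptive sparse multidimensional grid space.

The data's bounding hyperrectangle is quantized into ``R`` equal intervals
per axis, where ``R`` adapts to the sample size:

    R = floor(N ** (1/d) * f_R) + 1

Only occupied (nonnull) cells are stored, so memory scales with the number
of distinct occupied cells (at most ``min(N, R**d)``) rather than with the
full lattice — the property that makes the method viable in high dimension.

Interval convention: intervals are half-open ``[sc(j-1), sc(j))`` except the
last one per axis, which is closed so the axis maximum belongs to interval
``R``.  Locations are 1-based integer vectors; the linear cell number is the
mixed-radix index

    i = sum_j (c_j - 1) * R**(j-1) + 1

computed in arbitrary-precision Python integers so keys never collide even
when ``R**d`` overflows machine words.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PointSet",
    "CoordinateSequences",
    "GridCell",
    "GridSpace",
    "compute_resolution",
    "build_coordinate_sequences",
    "locate_point",
    "locate_points",
    "location_to_cell_number",
    "cell_number_to_location",
    "build_grid",
    "cell_center",
]


@dataclass(frozen=True)
class PointSet:
    """An ``N x d`` numeric data matrix with optional ground-truth labels.

    ``ids`` are stable 1-based point identifiers that survive filtering
    (denoising keeps the original ids of retained points).
    """

    points: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    true_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts.reshape(-1, 1)
        if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] < 1:
            raise ValueError("points must be a nonempty N x d matrix")
        if not np.all(np.isfinite(pts)):
            raise ValueError("all coordinates must be finite")
        object.__setattr__(self, "points", pts)
        ids = self.ids
        if ids is None:
            ids = np.arange(1, pts.shape[0] + 1)
        else:
            ids = np.asarray(ids)
            if ids.shape != (pts.shape[0],):
                raise ValueError("ids must have one entry per point")
        object.__setattr__(self, "ids", ids)
        if self.true_labels is not None:
            lab = np.asarray(self.true_labels)
            if lab.shape != (pts.shape[0],):
                raise ValueError("true_labels must have one entry per point")
            object.__setattr__(self, "true_labels", lab)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_dims(self) -> int:
        return self.points.shape[1]

    def subset(self, index: np.ndarray) -> "PointSet":
        """Row subset keeping original ids (and labels, if any)."""
        return PointSet(
            self.points[index],
            ids=self.ids[index],
            true_labels=None if self.true_labels is None else self.true_labels[index],
        )


@dataclass(frozen=True)
class CoordinateSequences:
    """Per-axis boundary sequences ``sc_i(0..R)`` dividing each axis into
    ``R`` equal-width intervals spanning [axis min, axis max].

    A degenerate axis (min == max) stores the repeated value; all points
    fall in interval 1 on that axis.
    """

    boundaries: np.ndarray  # shape (d, R+1)
    resolution: int

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 2 or b.shape[1] != self.resolution + 1:
            raise ValueError("boundaries must have shape (d, R+1)")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_dims(self) -> int:
        return self.boundaries.shape[0]

    @property
    def mins(self) -> np.ndarray:
        return self.boundaries[:, 0]

    @property
    def maxs(self) -> np.ndarray:
        return self.boundaries[:, -1]


@dataclass
class GridCell:
    """An occupied hyperrectangular bin.

    ``density`` is the member count: cells share a common volume, so the
    count is proportional to points per unit volume.
    """

    cell_number: int
    location: tuple
    members: np.ndarray  # indices into the meshed PointSet rows

    @property
    def density(self) -> int:
        return len(self.members)


@dataclass
class GridSpace:
    """Sparse grid: only nonnull cells are stored, keyed by cell number."""

    dimension: int
    resolution: int
    sequences: CoordinateSequences
    cells: dict  # cell_number -> GridCell
    _by_location: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_location:
            self._by_location = {c.location: num for num, c in self.cells.items()}

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_points(self) -> int:
        return sum(c.density for c in self.cells.values())

    def cell_at(self, location: Sequence[int]) -> Optional[GridCell]:
        num = self._by_location.get(tuple(location))
        return None if num is None else self.cells[num]

    def densities(self) -> np.ndarray:
        return np.array([c.density for c in self.cells.values()])

    def mean_density(self) -> float:
        if not self.cells:
            raise ValueError("grid has no nonnull cells")
        return self.n_points / self.n_cells


def compute_resolution(n_points: int, n_dims: int, resolution_coefficient: float) -> int:
    """Adaptive per-axis interval count ``R = floor(N**(1/d) * f_R) + 1``."""
    if n_points < 1 or n_dims < 1:
        raise ValueError("n_points and n_dims must be positive")
    if resolution_coefficient <= 0:
        raise ValueError("resolution_coefficient must be positive")
    r = math.floor(n_points ** (1.0 / n_dims) * resolution_coefficient) + 1
    return max(r, 1)


def build_coordinate_sequences(points: PointSet, resolution: int) -> CoordinateSequences:
    """Equal-width boundaries spanning [min, max] on each axis."""
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    pts = points.points
    mins = pts.min(axis=0)
    maxs = pts.max(axis=0)
    frac = np.linspace(0.0, 1.0, resolution + 1)
    bounds = mins[:, None] + (maxs - mins)[:, None] * frac[None, :]
    # pin exact endpoints; a degenerate axis collapses to the repeated value
    bounds[:, 0] = mins
    bounds[:, -1] = maxs
    return CoordinateSequences(bounds, resolution)


def locate_point(point: np.ndarray, seq: CoordinateSequences) -> tuple:
    """1-based interval index per axis for a single coordinate vector."""
    return tuple(int(v) for v in locate_points(np.atleast_2d(point), seq)[0])


def locate_points(points: np.ndarray, seq: CoordinateSequences) -> np.ndarray:
    """Vectorized point location: ``sc(j-1) <= x < sc(j)``, last interval
    closed at ``sc(R)``.  Points outside the grid bounds raise."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d, R = seq.n_dims, seq.resolution
    if pts.shape[1] != d:
        raise ValueError("point dimensionality does not match the grid")
    if np.any(pts < seq.mins - 0.0) or np.any(pts > seq.maxs + 0.0):
        raise ValueError("point outside grid bounds")
    loc = np.empty(pts.shape, dtype=np.int64)
    for i in range(d):
        b = seq.boundaries[i]
        if b[0] == b[-1]:  # degenerate axis
            loc[:, i] = 1
            continue
        # side='right' sends a point sitting on an interior boundary to the
        # right interval (half-open convention); the maximum is clamped to R.
        j = np.searchsorted(b, pts[:, i], side="right")
        loc[:, i] = np.clip(j, 1, R)
    return loc


def location_to_cell_number(location: Sequence[int], resolution: int, n_dims: int) -> int:
    """Mixed-radix linear index, exact for any ``R**d`` (Python ints)."""
    loc = tuple(int(c) for c in location)
    if len(loc) != n_dims:
        raise ValueError("location length does not match n_dims")
    num = 1
    weight = 1
    for c in loc:
        if not 1 <= c <= resolution:
            raise ValueError(f"location component {c} outside 1..{resolution}")
        num += (c - 1) * weight
        weight *= resolution
    return num


def cell_number_to_location(cell_number: int, resolution: int, n_dims: int) -> tuple:
    """Exact inverse of :func:`location_to_cell_number`."""
    if not 1 <= cell_number <= resolution**n_dims:
        raise ValueError("cell_number outside 1..R**d")
    rem = int(cell_number) - 1
    loc = []
    for _ in range(n_dims):
        rem, c = divmod(rem, resolution)
        loc.append(c + 1)
    return tuple(loc)


def build_grid(points: PointSet, resolution_coefficient: float) -> GridSpace:
    """Mesh a point set into a sparse adaptive grid in one pass.

    Every point becomes a member of exactly one cell, so cell densities sum
    to ``N``.
    """
    R = compute_resolution(points.n_points, points.n_dims, resolution_coefficient)
    seq = build_coordinate_sequences(points, R)
    locs = locate_points(points.points, seq)
    uniq, inverse = np.unique(locs, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    splits = np.searchsorted(inverse[order], np.arange(1, len(uniq)))
    groups = np.split(order, splits)
    cells = {}
    for row, members in zip(uniq, groups):
        loc = tuple(int(v) for v in row)
        num = location_to_cell_number(loc, R, points.n_dims)
        cells[num] = GridCell(num, loc, np.asarray(members))
    return GridSpace(points.n_dims, R, seq, cells)


def cell_center(cell: GridCell, points: PointSet) -> np.ndarray:
    """Arithmetic mean of the member coordinates (the cell's centre)."""
    if len(cell.members) == 0:
        raise ValueError("cell has no members")
    return points.points[cell.members].mean(axis=0)
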