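"""Density-threshold classification of grid cells.

Two adaptive thresholds, both multiples of the mean occupied-cell density,
drive the pipeline:

* noise threshold ``threN = mean_density * f_N`` — cells strictly below it
  are noise; their points are dropped (label 0) before clustering;
* halo threshold ``threH = mean_density * f_H`` — computed on the re-meshed
  (denoised) grid; cells strictly below it are peripheral (halo), the rest
  are core.  Cores seed and propagate clusters; peripherals are attached
  afterwards.

Strict ``<`` on both comparisons means a coefficient of 0 is an exact no-op
(no noise cells / every cell core).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Tuple

import numpy as np

from .grid import GridSpace, PointSet, build_grid

__all__ = [
    "PartitionThresholds",
    "CellPartition",
    "noise_threshold",
    "split_noise",
    "remesh",
    "halo_threshold",
    "split_core_peripheral",
]


@dataclass(frozen=True)
class PartitionThresholds:
    noise_threshold: float = 0.0
    halo_threshold: float = 0.0
    noise_coefficient: float = 0.0
    halo_coefficient: float = 0.0


@dataclass(frozen=True)
class CellPartition:
    """Disjoint noise / peripheral / core cell-number sets with the
    thresholds that produced them."""

    noise_cells: FrozenSet[int]
    peripheral_cells: FrozenSet[int]
    core_cells: FrozenSet[int]
    thresholds: PartitionThresholds


def noise_threshold(grid: GridSpace, noise_coefficient: float) -> float:
    """``threN``: mean nonnull-cell density times ``f_N``."""
    if noise_coefficient < 0:
        raise ValueError("noise_coefficient must be >= 0")
    return grid.mean_density() * noise_coefficient


def split_noise(grid: GridSpace, threshold: float, points: PointSet
                ) -> Tuple[FrozenSet[int], PointSet]:
    """Cells with density strictly below ``threshold`` are noise.

    Returns the noise cell-number set and the retained points (members of
    all other cells, original ids preserved).  If everything is noise the
    retained set is empty and the second element is ``None``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    noise = frozenset(num for num, c in grid.cells.items() if c.density < threshold)
    keep_rows = np.concatenate(
        [grid.cells[num].members for num in grid.cells if num not in noise]
        or [np.array([], dtype=int)]
    )
    if keep_rows.size == 0:
        return noise, None
    keep_rows = np.sort(keep_rows)
    return noise, points.subset(keep_rows)


def remesh(retained: PointSet, resolution_coefficient: float) -> GridSpace:
    """Fresh grid on the denoised points: both the axis ranges and the
    resolution are recomputed from the retained data."""
    if retained is None or retained.n_points == 0:
        raise ValueError("all points classified as noise; nothing to re-mesh")
    return build_grid(retained, resolution_coefficient)


def halo_threshold(grid: GridSpace, halo_coefficient: float) -> float:
    """``threH``: mean density of the post-denoise grid times ``f_H``."""
    if halo_coefficient < 0:
        raise ValueError("halo_coefficient must be >= 0")
    return grid.mean_density() * halo_coefficient


def split_core_peripheral(grid: GridSpace, threshold: float,
                          thresholds: PartitionThresholds = None) -> CellPartition:
    """Peripheral = density strictly below threshold; core = the rest."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    peripheral = frozenset(n for n, c in grid.cells.items() if c.density < threshold)
    core = frozenset(n for n in grid.cells if n not in peripheral)
    thr = thresholds or PartitionThresholds(halo_threshold=threshold)
    return CellPartition(frozenset(), peripheral, core, thr)
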