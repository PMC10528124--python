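"""Synthetic benchmark generators.

Four families cover the study conditions the clustering pipeline is
validated on:

* :func:`make_highdim_dense` — d+1 isotropic Gaussians at the origin and
  the standard basis vectors (high-dimensional dense layout);
* :func:`make_density_contrast` — four 2-d Gaussians whose point densities
  differ by a factor of ~25 (100/50/200/5000 points);
* :func:`make_noisy_blobs` — a Gaussian mixture plus uniform background
  noise at a controlled signal fraction (SNR = non-noise / total);
* :func:`make_gaussian_grid` — equal Gaussians on a square lattice
  (large-scale many-cluster layout).

Per-cluster sizes are exact, never multinomial draws, so count-based
checks are deterministic.  All randomness flows through an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grid import PointSet

__all__ = [
    "LabeledSample",
    "make_highdim_dense",
    "make_density_contrast",
    "make_noisy_blobs",
    "make_gaussian_grid",
]

# Default 4-blob layout for the noisy benchmark: well-separated unit
# Gaussians inside a common bounding box.
DEFAULT_BLOB_MEANS = ((0.0, 0.0), (8.0, 0.0), (0.0, 8.0), (8.0, 8.0))
DEFAULT_BLOB_VARIANCES = (1.0, 1.0, 1.0, 1.0)
DEFAULT_BBOX = ((-4.0, 12.0), (-4.0, 12.0))


@dataclass(frozen=True)
class LabeledSample:
    """A generated point set with ground truth and its provenance."""

    points: PointSet
    descriptor: dict

    @property
    def true_labels(self) -> np.ndarray:
        return self.points.true_labels


def _exact_sizes(n_total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment: sizes sum to n_total exactly and
    differ from the ideal shares by < 1."""
    ideal = n_total * weights / weights.sum()
    sizes = np.floor(ideal).astype(int)
    short = n_total - sizes.sum()
    if short > 0:
        order = np.argsort(-(ideal - sizes), kind="stable")
        sizes[order[:short]] += 1
    return sizes


def make_highdim_dense(d: int, per_cluster: int = 100, variance: float = 0.1,
                       seed: Optional[int] = None) -> LabeledSample:
    """d+1 clusters of ``per_cluster`` points each: cluster 0 around the
    origin, cluster i around the i-th standard basis vector, all isotropic
    Gaussian with the given per-coordinate variance."""
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(variance)
    blocks, labels = [], []
    for i in range(d + 1):
        mu = np.zeros(d)
        if i > 0:
            mu[i - 1] = 1.0
        blocks.append(rng.normal(mu, sigma, size=(per_cluster, d)))
        labels.append(np.full(per_cluster, i))
    ps = PointSet(np.vstack(blocks), true_labels=np.concatenate(labels))
    return LabeledSample(ps, {
        "name": "highdim_dense", "d": d, "per_cluster": per_cluster,
        "variance": variance, "seed": seed,
    })


def make_density_contrast(seed: Optional[int] = None) -> LabeledSample:
    """Four 2-d Gaussian clusters of 100, 50, 200 and 5000 points with means
    (0,0), (3,3), (4,17.3), (10,17.3) and variances 3, 3, 2, 3 — the two
    small clusters sit close together under the shadow of a cluster 25x
    denser."""
    rng = np.random.default_rng(seed)
    sizes = (100, 50, 200, 5000)
    means = ((0.0, 0.0), (3.0, 3.0), (4.0, 17.3), (10.0, 17.3))
    variances = (3.0, 3.0, 2.0, 3.0)
    blocks, labels = [], []
    for lab, (n, mu, var) in enumerate(zip(sizes, means, variances), start=1):
        blocks.append(rng.normal(mu, np.sqrt(var), size=(n, 2)))
        labels.append(np.full(n, lab))
    ps = PointSet(np.vstack(blocks), true_labels=np.concatenate(labels))
    return LabeledSample(ps, {
        "name": "density_contrast", "sizes": sizes, "means": means,
        "variances": variances, "seed": seed,
    })


def make_noisy_blobs(n_total: int = 5000, snr: float = 1.0,
                     means: Sequence = DEFAULT_BLOB_MEANS,
                     variances: Sequence = DEFAULT_BLOB_VARIANCES,
                     weights: Optional[Sequence] = None,
                     bbox: Sequence = DEFAULT_BBOX,
                     seed: Optional[int] = None) -> LabeledSample:
    """Gaussian blobs plus uniform background noise.

    ``round(n_total * snr)`` signal points are apportioned over the blobs;
    the remainder is uniform over ``bbox`` with noise label 0.
    """
    if not 0 < snr <= 1:
        raise ValueError("snr must be in (0, 1]")
    rng = np.random.default_rng(seed)
    means = np.atleast_2d(np.asarray(means, dtype=float))
    variances = np.broadcast_to(np.asarray(variances, dtype=float), (len(means),))
    w = np.ones(len(means)) if weights is None else np.asarray(weights, dtype=float)
    n_signal = int(round(n_total * snr))
    sizes = _exact_sizes(n_signal, w)
    blocks, labels = [], []
    for lab, (n, mu, var) in enumerate(zip(sizes, means, variances), start=1):
        if n == 0:
            continue
        blocks.append(rng.normal(mu, np.sqrt(var), size=(n, means.shape[1])))
        labels.append(np.full(n, lab))
    n_noise = n_total - n_signal
    if n_noise > 0:
        box = np.asarray(bbox, dtype=float)
        noise = rng.uniform(box[:, 0], box[:, 1], size=(n_noise, means.shape[1]))
        blocks.append(noise)
        labels.append(np.zeros(n_noise, dtype=int))
    ps = PointSet(np.vstack(blocks), true_labels=np.concatenate(labels))
    return LabeledSample(ps, {
        "name": "noisy_blobs", "n_total": n_total, "snr": snr,
        "n_noise": int(n_noise), "seed": seed,
    })


def make_gaussian_grid(n_clusters: int = 100, n_total: int = 10_000,
                       spacing: float = 10.0, variance: float = 1.0,
                       seed: Optional[int] = None) -> LabeledSample:
    """Equal isotropic Gaussians centred on a square lattice."""
    side = int(round(np.sqrt(n_clusters)))
    if side * side != n_clusters:
        raise ValueError("n_clusters must be a perfect square")
    rng = np.random.default_rng(seed)
    sizes = _exact_sizes(n_total, np.ones(n_clusters))
    blocks, labels = [], []
    lab = 0
    for gy in range(side):
        for gx in range(side):
            lab += 1
            mu = (gx * spacing, gy * spacing)
            n = sizes[lab - 1]
            blocks.append(rng.normal(mu, np.sqrt(variance), size=(n, 2)))
            labels.append(np.full(n, lab))
    ps = PointSet(np.vstack(blocks), true_labels=np.concatenate(labels))
    return LabeledSample(ps, {
        "name": "gaussian_grid", "n_clusters": n_clusters, "n_total": n_total,
        "spacing": spacing, "variance": variance, "seed": seed,
    })
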