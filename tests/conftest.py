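import numpy as np
import pytest

from cags import PointSet, make_noisy_blobs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blobs():
    """Two far-separated 2-d Gaussian blobs (centers 10 apart, sigma 0.5)."""
    r = np.random.default_rng(7)
    a = r.normal((0, 0), 0.5, size=(100, 2))
    b = r.normal((10, 10), 0.5, size=(100, 2))
    labels = np.repeat([1, 2], 100)
    return PointSet(np.vstack([a, b]), true_labels=labels)


# Table of densities used in worked threshold examples: 12 occupied cells
# holding 20 points in a 4x4 grid.
WORKED_DENSITIES = (1, 3, 1, 1, 2, 4, 2, 2, 1, 1, 1, 1)


def grid_from_densities(densities, d=2, R=4, seed=0):
    """Build a real GridSpace whose occupied-cell densities equal the given
    multiset, by placing points at distinct cell centres of a [0,R]^d box."""
    from cags import build_grid
    rng = np.random.default_rng(seed)
    # anchor points pin the data range to [0, R]^d so cells are unit boxes
    pts = [np.zeros(d), np.full(d, float(R))]
    locs = [(1,) * d, (R,) * d]
    taken = set(locs)
    free = [tuple(c) for c in np.ndindex(*(R,) * d)]
    free = [tuple(x + 1 for x in c) for c in free if tuple(x + 1 for x in c) not in taken]
    free = [free[i] for i in rng.permutation(len(free))]
    dens = list(densities)
    # the two anchors already occupy two cells with density 1 each
    assert dens.count(1) >= 2
    dens.remove(1), dens.remove(1)
    for target, loc in zip(dens, free):
        centre = np.array(loc, dtype=float) - 0.5
        for _ in range(target):
            pts.append(centre + rng.uniform(-0.2, 0.2, size=d))
    ps = PointSet(np.array(pts))
    grid = build_grid(ps, resolution_coefficient=(R - 1 + 0.5) / ps.n_points ** (1 / d))
    assert grid.resolution == R
    return ps, grid
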