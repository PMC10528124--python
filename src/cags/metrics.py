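"""External clustering-validity indices.

Five indices computed from the class x cluster contingency table:

* ``PUR`` — class-wise purity: each class contributes the largest joint
  count it attains in any cluster (note this is summed over *classes*, not
  the more common cluster-wise form; a single all-encompassing cluster
  therefore scores 1);
* ``CSM`` — cluster similarity measure: mean over classes of the best
  F-measure against any cluster;
* ``NMI`` — mutual information over the geometric mean of class and cluster
  entropies; undefined when either side has a single category;
* ``CluCE`` / ``ClaCE`` — cluster-conditional class entropy (normalized by
  log K) and class-conditional cluster entropy (normalized by log K*);
  0 for a perfect match, 1 for independent 2x2 tables.

All logarithm bases cancel; natural logs are used internally.  Degenerate
values are reported as ``None`` (serialized "err"), never coerced to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ContingencyTable",
    "MetricReport",
    "contingency",
    "purity",
    "csm",
    "nmi",
    "cluce",
    "clace",
    "evaluate",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Joint class x cluster counts with marginals."""

    counts: np.ndarray  # K x K*

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or np.any(c < 0):
            raise ValueError("counts must be a nonnegative 2-d array")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def class_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def cluster_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[1]

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T)


def contingency(true_labels, cluster_labels, exclude_noise: bool = False
                ) -> ContingencyTable:
    """Joint counts from two equal-length label sequences.

    Labels may be any hashables.  With ``exclude_noise`` points whose
    *predicted* label equals 0 are dropped; by default noise forms its own
    predicted cluster.
    """
    t = np.asarray(true_labels)
    c = np.asarray(cluster_labels)
    if t.shape != c.shape or t.ndim != 1 or len(t) < 1:
        raise ValueError("label sequences must be equal-length 1-d and nonempty")
    if exclude_noise:
        keep = c != 0
        t, c = t[keep], c[keep]
        if len(t) == 0:
            raise ValueError("all points are noise; nothing to evaluate")
    t_cats, t_idx = np.unique(t, return_inverse=True)
    c_cats, c_idx = np.unique(c, return_inverse=True)
    counts = np.zeros((len(t_cats), len(c_cats)))
    np.add.at(counts, (t_idx, c_idx), 1)
    return ContingencyTable(counts)


def purity(t: ContingencyTable) -> float:
    """Class-wise purity: (1/n) sum_k max_k* n_{k,k*}."""
    return float(t.counts.max(axis=1).sum() / t.n)


def csm(t: ContingencyTable, literal_normalization: bool = False) -> float:
    """Best per-class F-measure, averaged.

    Default normalization is 1/K so a perfect bijective match scores 1; the
    literal 1/n form is available via ``literal_normalization``.
    """
    nk = t.class_totals[:, None]
    nk_star = t.cluster_totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(nk + nk_star > 0, 2.0 * t.counts / (nk + nk_star), 0.0)
    best = f.max(axis=1)
    denom = t.n if literal_normalization else t.n_classes
    return float(best.sum() / denom)


def _entropy(totals: np.ndarray, n: float) -> float:
    p = totals[totals > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(t: ContingencyTable) -> Optional[float]:
    """Mutual information / geometric mean of the marginal entropies.

    ``None`` when either marginal entropy is zero (single class or single
    cluster) — the index is undefined there.
    """
    n = t.n
    h_class = _entropy(t.class_totals, n)
    h_clust = _entropy(t.cluster_totals, n)
    if h_class == 0.0 or h_clust == 0.0:
        return None
    outer = t.class_totals[:, None] * t.cluster_totals[None, :]
    nz = t.counts > 0
    mi = float((t.counts[nz] * np.log(n * t.counts[nz] / outer[nz])).sum() / n)
    return mi / math.sqrt(h_class * h_clust)


def cluce(t: ContingencyTable) -> Optional[float]:
    """Cluster-conditional class entropy, normalized by log K."""
    k = t.n_classes
    if k <= 1:
        return None
    n = t.n
    total = 0.0
    for j in range(t.n_clusters):
        col = t.counts[:, j]
        nks = col.sum()
        if nks == 0:
            continue
        p = col[col > 0] / nks
        total += (nks / n) * float(-(p * np.log(p)).sum())
    return float(total) / math.log(k)


def clace(t: ContingencyTable) -> Optional[float]:
    """Class-conditional cluster entropy, normalized by log K*."""
    return cluce(t.transpose())


@dataclass(frozen=True)
class MetricReport:
    pur: float
    csm: float
    nmi: Optional[float]
    cluce: Optional[float]
    clace: Optional[float]
    n: int
    K: int
    Kstar: int

    def to_dict(self) -> dict:
        def mark(v):
            return "err" if v is None else v
        return {
            "pur": self.pur, "csm": self.csm, "nmi": mark(self.nmi),
            "cluce": mark(self.cluce), "clace": mark(self.clace),
            "n": self.n, "K": self.K, "Kstar": self.Kstar,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def evaluate(true_labels, cluster_labels, exclude_noise: bool = False
             ) -> MetricReport:
    """All five indices from two label sequences."""
    t = contingency(true_labels, cluster_labels, exclude_noise=exclude_noise)
    return MetricReport(
        pur=purity(t), csm=csm(t), nmi=nmi(t),
        cluce=cluce(t), clace=clace(t),
        n=int(t.n), K=t.n_classes, Kstar=t.n_clusters,
    )
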