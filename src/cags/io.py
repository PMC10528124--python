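"""Reading point tables and writing cluster results.

Accepted input dialects:

* delimited tables with a header row (CSV/TSV), optionally carrying a label
  column named via ``label_column``;
* headerless whitespace/comma/tab-delimited numeric columns, the common
  distribution format of 2-d shape benchmarks (``x y [label]``) — with
  ``label_column="auto"`` an all-integer final column in a headerless file
  of >= 2 columns is treated as ground truth.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cluster import ClusterResult
from .grid import PointSet

logger = logging.getLogger("cags")

__all__ = ["read_point_table", "write_points", "write_result", "read_labels"]

_LABEL_NAMES = ("label", "class", "target", "truth", "cluster")

# documented guidance ranges; outside them a warning, never an error
GUIDANCE_RANGES = {
    "resolution_coefficient": (0.3, 3.0),
    "noise_coefficient": (0.0, 1.5),
    "halo_coefficient": (0.0, 3.0),
}


def warn_outside_guidance(name: str, value: float) -> None:
    rng = GUIDANCE_RANGES.get(name)
    if rng and not rng[0] <= value <= rng[1]:
        warnings.warn(
            f"{name}={value} is outside the usual range {rng}; "
            "results may be fragile", stacklevel=2)


def _sniff_sep(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return r"\s+"


def read_point_table(path: Union[str, Path], delimiter: Optional[str] = None,
                     label_column: Union[str, int, None] = "auto") -> PointSet:
    """Parse a numeric point table, optionally splitting off a label column."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    first = text.splitlines()[0]
    sep = delimiter or _sniff_sep(first)
    tokens = first.replace(sep if sep != r"\s+" else " ", " ").split()

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens if t)
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                     engine="python")
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    labels = None
    if label_column == "auto":
        if has_header:
            named = [c for c in df.columns
                     if str(c).strip().lower() in _LABEL_NAMES]
            if named:
                labels = df.pop(named[0]).to_numpy()
        elif df.shape[1] >= 2:
            last = df.iloc[:, -1]
            if np.issubdtype(last.dtype, np.number) and \
                    np.all(last == last.astype(int)):
                labels = df.pop(df.columns[-1]).to_numpy().astype(int)
    elif label_column is not None:
        col = label_column if label_column in df.columns else None
        if col is None and isinstance(label_column, int):
            col = df.columns[label_column]
        if col is None:
            raise ValueError(f"label column {label_column!r} not found")
        labels = df.pop(col).to_numpy()

    bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(bad):
        for col in bad:
            row = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row "
                f"{int(row[0]) + 1 + int(has_header)}")
    return PointSet(df.to_numpy(dtype=float), true_labels=labels)


def write_points(sample, path: Union[str, Path], delimiter: str = ",") -> None:
    """Write a labeled sample as a delimited table (feature columns x1..xd
    plus ``label``) with a JSON descriptor sidecar."""
    path = Path(path)
    ps = sample.points if hasattr(sample, "points") else sample
    cols = {f"x{i + 1}": ps.points[:, i] for i in range(ps.n_dims)}
    if ps.true_labels is not None:
        cols["label"] = ps.true_labels
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False)
    if hasattr(sample, "descriptor"):
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sample.descriptor, indent=2) + "\n")


def write_result(result: ClusterResult, points: PointSet,
                 prefix: Union[str, Path]) -> None:
    """Per-point labels CSV (``id,label``; 0 = noise) plus a JSON summary
    with cluster count, scales, center locations and mean cell densities."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    labels_path = prefix.with_suffix(".labels.csv")
    pd.DataFrame({"id": points.ids, "label": result.point_labels}
                 ).to_csv(labels_path, index=False)
    summary = {
        "n_clusters": result.n_clusters,
        "n_points": int(points.n_points),
        "n_noise_points": int((result.point_labels == 0).sum()),
        "clusters": [
            {
                "label": lab + 1,
                "scale": int(result.cluster_scale[lab]),
                "center_cell_location": list(
                    result.grid.cells[result.center_cells[lab]].location),
                "mean_cell_density": float(result.mean_cell_density[lab]),
            }
            for lab in range(result.n_clusters)
        ],
    }
    prefix.with_suffix(".summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    logger.info("wrote %s and %s", labels_path, prefix.with_suffix(".summary.json"))


def read_labels(path: Union[str, Path], column: Optional[str] = None) -> np.ndarray:
    """Read a label vector from a one- or two-column table (``[id,] label``)."""
    df = pd.read_csv(path)
    if column is not None:
        return df[column].to_numpy()
    if "label" in df.columns:
        return df["label"].to_numpy()
    return df.iloc[:, -1].to_numpy()
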