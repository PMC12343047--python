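"""Per-cell spatial proximity metrics.

Two measures quantify how close a cell is to each cell type within its
image:

* **abundance** ``n_{i,B}(r)`` — the number of type-B cells whose centroid
  lies within ``r`` microns of cell *i*;
* **distance** ``d_{i,B}(r)`` — the Euclidean distance from cell *i* to the
  nearest type-B cell, ceiling-capped at ``cap`` microns (default 200) to
  limit the leverage of isolated cells. When no B cell lies within the
  search radius the capped value is assigned, which keeps the cell in
  downstream regressions instead of discarding it; when no B cell exists in
  the image at all the entry is marked invalid.

A cell is never its own neighbour: for the self-pair (A = B) the cell is
excluded from both its own count and its own nearest-neighbour search.
Distances are centroid-to-centroid in the image's own coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_data import CellDataset

DEFAULT_RADIUS = 200.0
DEFAULT_CAP = 200.0

METRIC_KINDS = ("distance", "abundance")


@dataclass
class ProximityMatrix:
    """Cell x cell-type matrix of one proximity metric for a whole cohort.

    ``values`` is indexed by cell_id with one column per observed cell type;
    ``valid`` marks entries where the metric is defined (a distance to a
    type absent from the cell's image is undefined; the corresponding
    abundance is simply 0).
    """

    metric_kind: str
    radius: float
    cap: float | None
    values: pd.DataFrame
    valid: pd.DataFrame

    def column(self, target_type: str) -> pd.Series:
        return self.values[target_type]

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="cell_id")


def _coords(cells: pd.DataFrame) -> np.ndarray:
    return cells[["x", "y"]].to_numpy(dtype=float)


def abundance(image_cells: pd.DataFrame, target_type: str, r: float = DEFAULT_RADIUS) -> np.ndarray:
    """Count type-B cells within ``r`` microns of every cell in one image.

    The cell itself never contributes to its own count.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    xy = _coords(image_cells)
    is_b = (image_cells["cell_type"] == target_type).to_numpy()
    counts = np.zeros(len(image_cells), dtype=int)
    if not is_b.any():
        return counts
    tree = cKDTree(xy[is_b])
    counts = tree.query_ball_point(xy, r, return_length=True).astype(int)
    # a B cell finds itself at distance 0; remove the self-match
    counts[is_b] -= 1
    return counts


def nearest_distance(
    image_cells: pd.DataFrame,
    target_type: str,
    r: float = DEFAULT_RADIUS,
    cap: float = DEFAULT_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Capped nearest-neighbour distance to type B for every cell in one image.

    Returns ``(distances, valid)``. Distances are ``min(d_nn, cap)``; a cell
    with no B neighbour within ``r`` receives ``cap``. Cells for which the
    metric is undefined (no other B cell in the image) have ``valid`` False.
    """
    if r <= 0 or cap <= 0:
        raise ValueError("radius and cap must be positive")
    xy = _coords(image_cells)
    n = len(image_cells)
    is_b = (image_cells["cell_type"] == target_type).to_numpy()
    n_b = int(is_b.sum())
    dist = np.full(n, float(cap))
    valid = np.ones(n, dtype=bool)
    if n_b == 0:
        return dist, np.zeros(n, dtype=bool)
    tree = cKDTree(xy[is_b])
    # non-B cells: nearest B; B cells: nearest *other* B (skip the self-hit)
    d1, _ = tree.query(xy[~is_b], k=1)
    dist[~is_b] = np.minimum(d1, cap)
    if n_b == 1:
        # the lone B cell has no other B neighbour
        valid[is_b] = False
        dist[is_b] = np.nan
    else:
        d2, _ = tree.query(xy[is_b], k=2)
        dist[is_b] = np.minimum(d2[:, 1], cap)
    capped = np.minimum(dist, cap)
    # beyond the search radius the metric saturates at the cap
    with np.errstate(invalid="ignore"):
        capped[np.asarray(capped > r) & valid] = cap
    return capped, valid


def compute_proximity(
    dataset: CellDataset,
    metric_kind: str = "distance",
    r: float = DEFAULT_RADIUS,
    cap: float = DEFAULT_CAP,
) -> ProximityMatrix:
    """Batch one metric over every image and every observed cell type."""
    if metric_kind not in METRIC_KINDS:
        raise ValueError(
            f"unknown metric_kind {metric_kind!r}; expected one of {METRIC_KINDS}"
        )
    types = dataset.cell_types
    n = dataset.n_cells
    values = np.full((n, len(types)), np.nan)
    valid = np.zeros((n, len(types)), dtype=bool)
    row_pos = pd.Series(np.arange(n), index=dataset.cells.index)

    for image_id in dataset.image_ids:
        cells_img, _ = dataset.image_view(image_id)
        rows = row_pos[cells_img.index].to_numpy()
        for j, t in enumerate(types):
            if metric_kind == "abundance":
                values[rows, j] = abundance(cells_img, t, r)
                valid[rows, j] = True
            else:
                d, ok = nearest_distance(cells_img, t, r, cap)
                values[rows, j] = d
                valid[rows, j] = ok

    idx = pd.Index(dataset.cells["cell_id"], name="cell_id")
    return ProximityMatrix(
        metric_kind=metric_kind,
        radius=r,
        cap=cap if metric_kind == "distance" else None,
        values=pd.DataFrame(values, index=idx, columns=types),
        valid=pd.DataFrame(valid, index=idx, columns=types),
    )
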