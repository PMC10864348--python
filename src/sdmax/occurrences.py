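"""Species presence records and standard presence-data hygiene."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridStack

__all__ = ["OccurrenceSet", "read_occurrences", "dedupe_to_cells"]

log = logging.getLogger(__name__)


class EmptyOccurrenceError(ValueError):
    """No usable presence points remain."""


@dataclass
class OccurrenceSet:
    """Presence-only records for one species, in the raster stack's CRS."""

    species: str
    points: np.ndarray  # (m, 2) of (x, y)
    source_tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.isfinite(self.points).all():
            raise ValueError("occurrence points must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["lon", "lat"])
        df.insert(0, "species", self.species)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_occurrences(
    path: str | Path,
    species: str = "",
    x_col: str = "lon",
    y_col: str = "lat",
    species_col: str = "species",
) -> OccurrenceSet:
    """Read presence coordinates from a CSV file.

    The default columns are ``lon``/``lat``; other dialects (``longitude``/
    ``latitude``, ``x``/``y``) are handled by passing ``x_col``/``y_col``.
    Rows with non-finite coordinates are dropped with a logged warning. If
    ``species`` is given and a species column exists, only matching rows are
    kept; otherwise all rows are used.
    """
    df = pd.read_csv(path)
    missing = [c for c in (x_col, y_col) if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing coordinate column(s) {missing}; "
            f"available: {list(df.columns)}"
        )
    if species and species_col in df.columns:
        df = df[df[species_col] == species]
    xy = df[[x_col, y_col]].to_numpy(dtype=float)
    finite = np.isfinite(xy).all(axis=1)
    n_bad = int((~finite).sum())
    if n_bad:
        log.warning("%s: dropped %d rows with non-finite coordinates", path, n_bad)
    xy = xy[finite]
    if len(xy) == 0:
        raise EmptyOccurrenceError(f"{path}: no usable presence rows")
    return OccurrenceSet(species=species or "unknown", points=xy)


def dedupe_to_cells(occ: OccurrenceSet, stack: GridStack) -> OccurrenceSet:
    """Thin presences to at most one record per raster cell.

    Points falling on invalid (NoData) cells or outside the grid are dropped
    with a logged count. The first record in each occupied cell is kept and
    snapped to nothing — original coordinates are preserved.
    """
    rows, cols = stack.transform.point_to_cell(occ.points[:, 0], occ.points[:, 1])
    nrows, ncols = stack.shape
    inside = (rows >= 0) & (rows < nrows) & (cols >= 0) & (cols < ncols)
    mask = stack.valid_mask
    on_valid = np.zeros(len(occ), dtype=bool)
    on_valid[inside] = mask[rows[inside], cols[inside]]
    n_dropped = int((~on_valid).sum())
    if n_dropped:
        log.warning(
            "%s: dropped %d points on invalid or out-of-grid cells",
            occ.species, n_dropped,
        )
    flat = rows[on_valid] * ncols + cols[on_valid]
    _, first = np.unique(flat, return_index=True)
    keep_idx = np.flatnonzero(on_valid)[np.sort(first)]
    if len(keep_idx) == 0:
        raise EmptyOccurrenceError(
            f"{occ.species}: all points fall on invalid cells"
        )
    tags = (
        [occ.source_tags[i] for i in keep_idx] if occ.source_tags else None
    )
    return OccurrenceSet(occ.species, occ.points[keep_idx], tags)
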