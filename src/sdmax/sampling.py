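"""Predictor extraction at points and uniform background sampling.

Presence-only modelling contrasts the conditions at presence points with a
background sample characterizing what the landscape offers; both live in a
:class:`SampleTable` keyed by layer name so downstream stages never touch
raster geometry again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridStack
from .occurrences import OccurrenceSet

__all__ = ["SampleTable", "extract_values", "sample_background", "DEFAULT_BACKGROUND_SIZE"]

log = logging.getLogger(__name__)

#: common practice for presence-background models; configurable everywhere
DEFAULT_BACKGROUND_SIZE = 10_000


@dataclass
class SampleTable:
    """Rows of raw predictor values at presence or background cells."""

    kind: str  # "presence" | "background"
    data: pd.DataFrame  # one column per layer, raw (unscaled) values
    cell_index: np.ndarray  # flattened valid-cell index per row

    def __post_init__(self) -> None:
        if self.kind not in ("presence", "background"):
            raise ValueError("kind must be 'presence' or 'background'")
        self.cell_index = np.asarray(self.cell_index, dtype=int)
        if len(self.cell_index) != len(self.data):
            raise ValueError("cell_index must align with data rows")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def layer_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, layers: list[str]) -> "SampleTable":
        return SampleTable(self.kind, self.data[list(layers)].copy(), self.cell_index)

    def take(self, idx: np.ndarray) -> "SampleTable":
        return SampleTable(
            self.kind, self.data.iloc[idx].reset_index(drop=True), self.cell_index[idx]
        )


class OutOfExtentError(ValueError):
    """One or more points fall outside the raster extent."""


def extract_values(stack: GridStack, points: np.ndarray | OccurrenceSet,
                   kind: str = "presence") -> SampleTable:
    """Sample every layer at each point's containing cell (cell-center value).

    Rows align with the input point order. Points outside the raster extent
    raise :class:`OutOfExtentError` listing the offending indices; points on
    NoData cells yield NaN rows (callers normally dedupe/drop beforehand).
    """
    if isinstance(points, OccurrenceSet):
        points = points.points
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    rows, cols = stack.transform.point_to_cell(points[:, 0], points[:, 1])
    nrows, ncols = stack.shape
    outside = (rows < 0) | (rows >= nrows) | (cols < 0) | (cols >= ncols)
    if outside.any():
        raise OutOfExtentError(
            f"points outside raster extent at indices {np.flatnonzero(outside).tolist()}"
        )
    vals = stack.values[:, rows, cols].T  # (n_points, n_layers)
    df = pd.DataFrame(vals, columns=stack.layer_names)
    return SampleTable(kind=kind, data=df, cell_index=rows * ncols + cols)


def sample_background(
    stack: GridStack,
    n: int = DEFAULT_BACKGROUND_SIZE,
    seed: int | np.random.Generator = 0,
) -> SampleTable:
    """Draw ``n`` background cells uniformly without replacement.

    If ``n`` exceeds the number of valid cells, every valid cell is used once
    and a warning is logged. Deterministic under a fixed seed and invariant
    to layer order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    valid = stack.valid_indices
    if len(valid) == 0:
        raise ValueError("stack has no valid cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n >= len(valid):
        if n > len(valid):
            log.warning(
                "requested %d background cells but only %d valid; using all",
                n, len(valid),
            )
        chosen = valid
    else:
        chosen = valid[rng.choice(len(valid), size=n, replace=False)]
    chosen = np.sort(chosen)
    flat = stack.values.reshape(stack.n_layers, -1)
    df = pd.DataFrame(flat[:, chosen].T, columns=stack.layer_names)
    return SampleTable(kind="background", data=df, cell_index=chosen)
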