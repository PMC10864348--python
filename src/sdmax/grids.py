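"""Co-registered raster stacks.

A :class:`GridStack` holds named, co-registered single-band rasters on a
common square-cell grid. Rasters are read and written as ESRI ASCII grids
(``.asc``), the plain-text format used by the Java MaxEnt tool and the
``dismo`` R package. NoData cells in any layer invalidate the cell for all
layers: the model downstream needs a complete predictor vector per cell.

Grid geometry convention: cells are half-open boxes. Cell (row r, col c)
owns points with x in [x0 + c*cell, x0 + (c+1)*cell) and
y in (ytop - (r+1)*cell, ytop - r*cell], where (x0, ytop) is the top-left
corner of the grid. Values are point-sampled at cell centers; there is no
interpolation and no reprojection.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridTransform",
    "GridStack",
    "GridAlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_raster_stack",
]

#: relative tolerance (in cells) for declaring two grids co-registered
ALIGN_TOL = 1e-6


class GridAlignmentError(ValueError):
    """Raised when layers do not share shape, origin and cell size."""


@dataclass(frozen=True)
class GridTransform:
    """Georeferencing of a square-cell grid: top-left corner + cell size."""

    x_origin: float  # west edge of the grid
    y_origin: float  # north edge of the grid
    cell: float      # side length of the (square) cells

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        x = self.x_origin + (np.asarray(col) + 0.5) * self.cell
        y = self.y_origin - (np.asarray(row) + 0.5) * self.cell
        return x, y

    def point_to_cell(self, x, y):
        """Map points to (row, col) under the half-open cell convention."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell).astype(int)
        row = np.floor((self.y_origin - y) / self.cell).astype(int)
        # top edge y == y_origin belongs to row 0; floor gives 0 already,
        # but guard against -0.0 artifacts
        row = np.where((self.y_origin - y) == 0.0, 0, row)
        return row, col

    def close_to(self, other: "GridTransform") -> bool:
        tol = ALIGN_TOL * self.cell
        return (
            abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell - other.cell) <= tol
        )


@dataclass
class GridStack:
    """Named, co-registered raster layers sharing a validity mask.

    ``values`` is a ``(n_layers, rows, cols)`` float array with NaN marking
    NoData. A cell is valid only where every layer is finite.
    """

    layer_names: list[str]
    values: np.ndarray
    transform: GridTransform
    crs_label: str = ""
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_layers, rows, cols)")
        if len(self.layer_names) != self.values.shape[0]:
            raise ValueError("one name per layer required")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer names must be unique")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where every layer is finite."""
        return np.isfinite(self.values).all(axis=0)

    @property
    def valid_indices(self) -> np.ndarray:
        """Flattened (row-major) indices of valid cells."""
        return np.flatnonzero(self.valid_mask.ravel())

    def layer(self, name: str) -> np.ndarray:
        try:
            i = self.layer_names.index(name)
        except ValueError:
            raise KeyError(f"no layer named {name!r}") from None
        return self.values[i]

    def valid_matrix(self) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix of predictor values."""
        flat = self.values.reshape(self.n_layers, -1)
        return flat[:, self.valid_indices].T

    def cell_centers(self, flat_index: np.ndarray):
        rows, cols = np.unravel_index(flat_index, self.shape)
        return self.transform.cell_center(rows, cols)

    def copy(self) -> "GridStack":
        return GridStack(
            list(self.layer_names),
            self.values.copy(),
            self.transform,
            self.crs_label,
            self.nodata_value,
        )

    # -- I/O --------------------------------------------------------------
    def write(self, directory: str | Path, fmt: str = "%.10g") -> list[Path]:
        """Write one ``<name>.asc`` per layer; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, layer in zip(self.layer_names, self.values):
            p = directory / f"{name}.asc"
            write_ascii_grid(p, layer, self.transform, self.nodata_value, fmt)
            paths.append(p)
        return paths


def write_ascii_grid(
    path: str | Path,
    layer: np.ndarray,
    transform: GridTransform,
    nodata: float = -9999.0,
    fmt: str = "%.10g",
) -> None:
    """Write a single layer as an ESRI ASCII grid (NaN -> NODATA_value)."""
    layer = np.asarray(layer, dtype=float)
    rows, cols = layer.shape
    yll = transform.y_origin - rows * transform.cell
    out = np.where(np.isfinite(layer), layer, nodata)
    buf = io.StringIO()
    buf.write(f"ncols {cols}\n")
    buf.write(f"nrows {rows}\n")
    buf.write(f"xllcorner {transform.x_origin!r}\n")
    buf.write(f"yllcorner {yll!r}\n")
    buf.write(f"cellsize {transform.cell!r}\n")
    buf.write(f"NODATA_value {nodata!r}\n")
    np.savetxt(buf, out, fmt=fmt)
    Path(path).write_text(buf.getvalue())


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridTransform, float]:
    """Read an ESRI ASCII grid; NODATA becomes NaN.

    Returns ``(layer, transform, nodata_value)``.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    lines = text.splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner",
            "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise IOError(f"{path}: missing ASCII-grid header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    body = "\n".join(lines[i:])
    data = np.loadtxt(io.StringIO(body), dtype=float)
    data = np.atleast_2d(data)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (rows, cols):
        raise IOError(
            f"{path}: body shape {data.shape} does not match header ({rows}, {cols})"
        )
    data = np.where(data == nodata, np.nan, data)
    transform = GridTransform(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + rows * header["cellsize"],
        cell=header["cellsize"],
    )
    return data, transform, nodata


def read_raster_stack(
    paths: list[str | Path],
    names: list[str] | None = None,
    crs_label: str = "",
) -> GridStack:
    """Read single-band rasters into a co-registered :class:`GridStack`.

    All rasters must share shape, cell size and origin to within
    ``ALIGN_TOL`` of a cell; the first mismatching layer is named in the
    error. The stack's validity mask is the conjunction of per-layer
    finiteness.
    """
    if not paths:
        raise ValueError("need at least one raster file")
    paths = [Path(p) for p in paths]
    if names is None:
        names = [p.stem for p in paths]
    if len(names) != len(paths):
        raise ValueError("one name per path required")

    layers = []
    ref_transform: GridTransform | None = None
    ref_shape: tuple[int, int] | None = None
    nodata = -9999.0
    for name, p in zip(names, paths):
        layer, transform, nd = read_ascii_grid(p)
        if ref_transform is None:
            ref_transform, ref_shape, nodata = transform, layer.shape, nd
        else:
            if layer.shape != ref_shape or not transform.close_to(ref_transform):
                raise GridAlignmentError(
                    f"layer {name!r} ({p}) is not aligned with {names[0]!r}: "
                    f"shape {layer.shape} vs {ref_shape}, "
                    f"transform {transform} vs {ref_transform}"
                )
        layers.append(layer)
    return GridStack(
        layer_names=list(names),
        values=np.stack(layers),
        transform=ref_transform,
        crs_label=crs_label,
        nodata_value=nodata,
    )
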