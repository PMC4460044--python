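"""Gridded raster containers and plain-text (ESRI ASCII) raster I/O.

All rasters in one analysis share a common grid: square cells of
``cell_size`` metres, projected coordinates, origin at the lower-left
corner of the grid.  Arrays are stored row 0 = northernmost row, matching
the ESRI ASCII grid layout.  Points are mapped to cells by flooring
``(p - origin) / cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Raster",
    "CategoricalRaster",
    "read_ascii_grid",
    "write_ascii_grid",
    "points_to_cells",
    "cell_centres",
]

ASPECT_LEGEND = {0: "flat", 1: "N", 2: "NE", 3: "E", 4: "SE",
                 5: "S", 6: "SW", 7: "W", 8: "NW"}


@dataclass
class Raster:
    """A single-band gridded variable.

    Parameters
    ----------
    values : 2-D float array, row 0 = north.
    cell_size : cell edge length in metres (> 0).
    origin : (x, y) of the grid's lower-left corner in projected metres.
    nodata_mask : boolean array, True where the cell carries no data.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D grid")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def aligned_with(self, other: "Raster") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.cell_size, other.cell_size)
                and np.allclose(self.origin, other.origin))

    def require_aligned(self, other: "Raster") -> None:
        if not self.aligned_with(other):
            raise ValueError("rasters are not grid-aligned")

    def copy_with(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "Raster":
        return Raster(np.asarray(values, dtype=float), self.cell_size,
                      self.origin, self.nodata_mask.copy() if nodata_mask is None else nodata_mask)


@dataclass
class CategoricalRaster(Raster):
    """Integer-coded raster with a legend mapping codes to class names."""

    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        codes = np.unique(self.values[self.valid]).astype(int)
        missing = [int(c) for c in codes if int(c) not in self.legend]
        if missing:
            raise ValueError(f"codes missing from legend: {missing}")

    @property
    def codes(self) -> np.ndarray:
        return self.values.astype(int)


def points_to_cells(points: np.ndarray, raster: Raster) -> tuple[np.ndarray, np.ndarray]:
    """Map (x, y) points to (row, col) indices on ``raster``'s grid.

    Points outside the grid get row/col of -1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x0, y0 = raster.origin
    cs = raster.cell_size
    nrows, ncols = raster.shape
    col = np.floor((pts[:, 0] - x0) / cs).astype(int)
    row_from_bottom = np.floor((pts[:, 1] - y0) / cs).astype(int)
    row = nrows - 1 - row_from_bottom
    bad = (col < 0) | (col >= ncols) | (row < 0) | (row >= nrows)
    row[bad] = -1
    col[bad] = -1
    return row, col


def cell_centres(raster: Raster) -> tuple[np.ndarray, np.ndarray]:
    """Return (x, y) coordinate grids of every cell centre."""
    nrows, ncols = raster.shape
    x0, y0 = raster.origin
    cs = raster.cell_size
    x = x0 + (np.arange(ncols) + 0.5) * cs
    y = y0 + (nrows - np.arange(nrows) - 0.5) * cs
    return np.meshgrid(x, y)


def read_ascii_grid(path: str | Path, legend: dict[int, str] | None = None) -> Raster:
    """Read an ESRI ASCII grid (.asc).  Pass ``legend`` to get a CategoricalRaster."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"missing header field {key} in {path}")
    body = "\n".join(lines[i:])
    values = np.array(body.split(), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.size != nrows * ncols:
        raise ValueError(f"expected {nrows * ncols} values, got {values.size}")
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    mask = np.zeros(values.shape, dtype=bool) if nodata is None else values == nodata
    origin = (header["xllcorner"], header["yllcorner"])
    if legend is not None:
        return CategoricalRaster(values, header["cellsize"], origin, mask, legend=legend)
    return Raster(values, header["cellsize"], origin, mask)


def write_ascii_grid(raster: Raster, path: str | Path, nodata_value: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid.

    Integer-valued grids are written as integers so the round-trip is
    bit-exact; float grids use repr-precision decimals.
    """
    path = Path(path)
    vals = np.where(raster.nodata_mask, nodata_value, raster.values)
    is_int = np.all(vals == np.round(vals)) and np.all(np.abs(vals) < 2**53)
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]!r}\n")
        fh.write(f"yllcorner {raster.origin[1]!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"nodata_value {nodata_value!r}\n")
        for row in vals:
            if is_int:
                fh.write(" ".join(str(int(v)) for v in row))
            else:
                fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
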