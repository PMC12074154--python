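"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

All geometry lives in one local projected coordinate system in meters.  A
raster is an ``(nrows, ncols)`` float array anchored at its north-west corner;
row 0 is the northernmost row.  Files are written as standard Arc/Info ASCII
grids so every artifact stays human-readable text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "GridSpec", "read_ascii", "write_ascii"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid: NW corner, cell size, and shape."""

    x0: float
    y0: float  # north edge
    cell: float
    nrows: int
    ncols: int
    crs: str = "local-m"

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys) 1-D arrays of column / row cell-center coordinates."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 - (np.arange(self.nrows) + 0.5) * self.cell
        return xs, ys

    def index_of(self, x, y):
        """Row/col of the cells containing (x, y); half-open cells."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell).astype(int)
        row = np.floor((self.y0 - np.asarray(y)) / self.cell).astype(int)
        return row, col


@dataclass
class Raster:
    data: np.ndarray
    grid: GridSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.grid is None:
            self.grid = GridSpec(0.0, self.data.shape[0] * 1.0, 1.0, *self.data.shape)
        if self.data.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError(
                f"data shape {self.data.shape} != grid "
                f"({self.grid.nrows}, {self.grid.ncols})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "Raster") -> bool:
        g, h = self.grid, other.grid
        return (
            g.nrows == h.nrows
            and g.ncols == h.ncols
            and abs(g.x0 - h.x0) < 1e-9
            and abs(g.y0 - h.y0) < 1e-9
            and abs(g.cell - h.cell) < 1e-9
            and g.crs == h.crs
        )

    def value_at(self, x, y):
        """Nearest-cell value(s) at coordinates; NaN outside the extent."""
        row, col = self.grid.index_of(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        out = np.full(row.shape, np.nan)
        ok = (row >= 0) & (row < self.grid.nrows) & (col >= 0) & (col < self.grid.ncols)
        out[ok] = self.data[row[ok], col[ok]]
        return out if out.size > 1 else float(out[0])


def write_ascii(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (NODATA encoded as -9999)."""
    g = raster.grid
    yll = g.y0 - g.nrows * g.cell
    data = np.where(np.isfinite(raster.data), raster.data, -9999.0)
    header = (
        f"ncols {g.ncols}\nnrows {g.nrows}\n"
        f"xllcorner {g.x0!r}\nyllcorner {yll!r}\n"
        f"cellsize {g.cell!r}\nNODATA_value -9999\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")


def read_ascii(path, crs: str = "local-m") -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", -9999.0)
    data[data == nodata] = np.nan
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    y0 = header["yllcorner"] + nrows * cell
    return Raster(data, GridSpec(header["xllcorner"], y0, cell, nrows, ncols, crs))
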