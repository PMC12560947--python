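"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

All layers in this package live on small projected grids (meters) with
square cells, so a lightweight container is sufficient: a 2-D float array
plus an affine placement (lower-left corner, cell size).  Grid agreement
between layers is enforced strictly — a mismatch is always a hard error,
never a silent resample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Grid", "Raster", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Placement of a square-celled raster in a projected CRS (meters).

    Row 0 of the data array is the *top* row of the map, following the
    usual raster convention; ``yll`` is the y coordinate of the lower-left
    corner of the lower-left cell.
    """

    ncols: int
    nrows: int
    xll: float
    yll: float
    cellsize: float

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as 2-D arrays matching the data layout."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing a projected point."""
        col = int(np.floor((x - self.xll) / self.cellsize))
        row = int(self.nrows - 1 - np.floor((y - self.yll) / self.cellsize))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        try:
            self.rowcol(x, y)
            return True
        except ValueError:
            return False


@dataclass
class Raster:
    """A single-band raster: data values on a :class:`Grid`. NaN = missing."""

    grid: Grid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid "
                f"({self.grid.nrows}, {self.grid.ncols})"
            )

    def same_grid(self, other: "Raster") -> bool:
        return self.grid == other.grid


def require_same_grid(*rasters: Raster) -> Grid:
    """Verify all rasters share one grid; return it.  Mismatch is fatal."""
    grids = {r.grid for r in rasters}
    if len(grids) != 1:
        raise ValueError(f"layers on different grids: {grids}")
    return rasters[0].grid


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc), NaN encoded as the nodata value."""
    g = raster.grid
    data = np.where(np.isnan(raster.data), _NODATA, raster.data)
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.xll!r}\n"
        f"yllcorner {g.yll!r}\n"
        f"cellsize {g.cellsize!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc); nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos if len(header) == 6 else 0)
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {key!r}")
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    grid = Grid(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    return Raster(grid, data)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
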