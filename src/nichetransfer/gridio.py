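"""Plain-text raster I/O (ESRI ASCII grid).

Grids are float arrays indexed [row, col], row 0 at the top of the map,
matching the ASCII-grid convention that the first data row is the
northernmost. All other modules treat grids as bare numpy arrays plus a
:class:`GridGeometry`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridGeometry", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Shared geometry of a raster stack: shape, cell size, origin."""

    rows: int
    cols: int
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError(
                f"grid dimensions must be positive, got {self.rows}x{self.cols}"
            )

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.rows) & (col >= 0) & (col < self.cols)


def write_ascii_grid(path: str | Path, grid: np.ndarray,
                     geometry: GridGeometry | None = None) -> None:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    geom = geometry or GridGeometry(*grid.shape)
    body = np.where(np.isfinite(grid), grid, _NODATA)
    header = (
        f"ncols {geom.cols}\n"
        f"nrows {geom.rows}\n"
        f"xllcorner {geom.xllcorner}\n"
        f"yllcorner {geom.yllcorner}\n"
        f"cellsize {geom.cellsize}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    nodata = header.get("nodata_value", _NODATA)
    grid = np.where(grid == nodata, np.nan, grid)
    geom = GridGeometry(
        rows=int(header.get("nrows", grid.shape[0])),
        cols=int(header.get("ncols", grid.shape[1])),
        cellsize=header.get("cellsize", 1.0),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
    )
    if grid.shape != (geom.rows, geom.cols):
        raise ValueError(f"grid shape {grid.shape} does not match header")
    return grid, geom
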