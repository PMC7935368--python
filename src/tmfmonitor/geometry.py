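"""Grid geometry and plain-text raster I/O.

Category and metric rasters are exchanged as ESRI ASCII grids (``.asc``), a
text format readable by every mainstream GIS.  Geometry is a north-up,
axis-aligned grid described by the coordinates of the upper-left corner and a
square cell size; coordinates may be projected metres or geographic degrees
(``geographic=True``), which the hotspot aggregation requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """North-up raster grid.

    Parameters
    ----------
    rows, cols:
        Grid shape.
    x_origin, y_origin:
        Coordinates of the *upper-left corner* of the upper-left cell.
    cell_size:
        Square cell size in the units of the coordinate axes.
    geographic:
        True when x/y are longitude/latitude degrees.
    """

    rows: int
    cols: int
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 30.0
    geographic: bool = False

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped (rows, cols)."""
        xs = self.x_origin + (np.arange(self.cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(self.rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def same_grid(self, other: "GridGeometry") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
            and self.geographic == other.geographic
        )


def write_ascii_grid(
    path: str | Path,
    data: np.ndarray,
    geometry: GridGeometry,
    nodata: float = -9999,
) -> None:
    """Write a single-band raster as an ESRI ASCII grid."""
    data = np.asarray(data)
    if data.shape != geometry.shape:
        raise ValueError(f"data shape {data.shape} != grid shape {geometry.shape}")
    path = Path(path)
    yll = geometry.y_origin - geometry.rows * geometry.cell_size
    header = (
        f"ncols {geometry.cols}\n"
        f"nrows {geometry.rows}\n"
        f"xllcorner {geometry.x_origin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {nodata}\n"
    )
    if np.issubdtype(data.dtype, np.integer):
        fmt = "%d"
    else:
        fmt = "%.6g"
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(
    path: str | Path, geographic: bool = False
) -> tuple[np.ndarray, GridGeometry, float]:
    """Read an ESRI ASCII grid; returns (data, geometry, nodata)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(rows, cols)
    cell = header["cellsize"]
    geom = GridGeometry(
        rows=rows,
        cols=cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + rows * cell,
        cell_size=cell,
        geographic=geographic,
    )
    return data, geom, header["nodata_value"]
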