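"""Regular-grid elevation rasters (DSM / DTM / CHM).

A :class:`RasterGrid` is a rectangular array of elevations (meters) on a planar
coordinate system. ``origin`` is the *lower-left corner* of the grid, so the
center of cell ``[i, j]`` sits at ``(origin_x + (j + 0.5) * pixel_size,
origin_y + (i + 0.5) * pixel_size)``; row 0 is the southernmost row. Nodata
cells hold the ``nodata`` sentinel and are excluded from all statistics.

Rasters are written as single-band float32 TIFF with the grid geometry
(origin, pixel size, nodata) stored as JSON in the ImageDescription tag, which
round-trips losslessly through :func:`write_tiff` / :func:`read_tiff`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import GridAlignmentError

__all__ = ["RasterGrid", "write_tiff", "read_tiff"]

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    values: np.ndarray
    origin: tuple[float, float]
    pixel_size: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid extent."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.pixel_size, y0 + ny * self.pixel_size)

    def x_centers(self) -> np.ndarray:
        nx = self.values.shape[1]
        return self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        ny = self.values.shape[0]
        return self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate arrays, broadcast to the grid shape."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds real data."""
        return self.values != self.nodata

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_geometry(self, other: "RasterGrid") -> None:
        if not self.same_geometry(other):
            raise GridAlignmentError(
                f"grids differ: shape {self.shape} vs {other.shape}, "
                f"origin {self.origin} vs {other.origin}, "
                f"pixel {self.pixel_size} vs {other.pixel_size}"
            )

    def subtract(self, other: "RasterGrid") -> "RasterGrid":
        """Cell-wise difference self − other, propagating nodata from either."""
        self.require_same_geometry(other)
        out = self.values - other.values
        bad = ~self.mask() | ~other.mask()
        out[bad] = self.nodata
        return RasterGrid(out, self.origin, self.pixel_size, self.nodata)

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.values.copy(), self.origin, self.pixel_size, self.nodata)


def write_tiff(raster: RasterGrid, path) -> None:
    meta = {
        "origin": list(raster.origin),
        "pixel_size": raster.pixel_size,
        "nodata": raster.nodata,
    }
    tifffile.imwrite(
        path,
        raster.values.astype(np.float32),
        description=json.dumps(meta),
    )


def read_tiff(path) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        meta = json.loads(page.description)
        values = page.asarray().astype(float)
    return RasterGrid(
        values,
        origin=tuple(meta["origin"]),
        pixel_size=float(meta["pixel_size"]),
        nodata=float(meta["nodata"]),
    )
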