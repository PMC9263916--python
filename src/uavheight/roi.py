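"""Regions of interest and zonal percentile statistics.

Two kinds of ROI are used:

* **inner** ROIs — axis-aligned rectangles over the plant blocks of each
  measured row. One rectangle per (measured row, block); the rectangle over
  the middle block spans the five measured plants (plus half a plant spacing
  at each end) and carries ``measurement=True``: its 98th percentile on a
  crop height model is the plot-level SfM height of that row.
* **outer** ROIs — a closed ring of rectangles just outside the analysis
  region, sampling bare ground for the polynomial-DTM method. Four
  ``ring_depth`` × ``ring_depth`` corner squares plus, per side, an even
  division into pieces of length ≈ ``edge_unit`` (gap-free). For the default
  35.5 × 54 m region with 1 m units and 0.5 m depth this yields 180
  rectangles.

Pixel membership follows the pixel-center rule, half-open on the max edges:
a pixel belongs to a rectangle iff ``xmin <= cx < xmax`` and
``ymin <= cy < ymax``. Percentiles interpolate linearly between order
statistics (position ``q/100 * (N-1)`` on the sorted sample).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import box

from .errors import DegradedROIError, EmptyROIError
from .field import FieldLayout
from .raster import RasterGrid

__all__ = [
    "ROI",
    "PixelSample",
    "build_inner_rois",
    "build_outer_rois",
    "extract_pixels",
    "percentile",
    "median_center",
    "rois_to_geojson",
    "write_geojson",
    "read_geojson",
    "write_roi_centroids",
]

#: an ROI with more than this fraction of nodata pixels is rejected
NODATA_TOLERANCE = 0.5


@dataclass(frozen=True)
class ROI:
    id: str
    kind: str  # "inner" | "outer"
    rect: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)
    group: int | None = None  # spatial CV group, inner ROIs only
    measurement: bool = False  # True for the measured-plant block rectangle

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.rect
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"ROI {self.id} has non-positive area: {self.rect}")

    @property
    def centroid(self) -> tuple[float, float]:
        xmin, ymin, xmax, ymax = self.rect
        return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)

    def polygon(self):
        return box(*self.rect)


@dataclass(frozen=True)
class PixelSample:
    """Valid pixel values of one ROI plus the fraction that was nodata."""

    values: np.ndarray
    nodata_fraction: float
    n_total: int


def build_inner_rois(layout: FieldLayout) -> list[ROI]:
    """One rectangle per (measured row, block), width = row spacing.

    Block rectangles span their plants plus half a plant spacing at each end;
    the measured block's rectangle spans only the five measured plants. All
    rectangles of one row abut without overlap, and rows are separated by the
    row spacing, so the full inner set is pairwise disjoint.
    """
    half_w = layout.row_spacing / 2.0
    half_s = layout.plant_spacing / 2.0
    blocks = layout.block_plant_indices()
    measured = layout.measured_plant_indices()
    rois = []
    for row in layout.measured_rows():
        ys = layout.plant_y_positions(row.plot)
        for b, plant_idx in enumerate(blocks):
            if b == layout.measured_block:
                idx = measured
            else:
                idx = plant_idx
            rect = (
                row.x_center - half_w,
                float(ys[idx[0]] - half_s),
                row.x_center + half_w,
                float(ys[idx[-1]] + half_s),
            )
            rois.append(
                ROI(
                    id=f"{row.row_id}B{b}",
                    kind="inner",
                    rect=rect,
                    group=row.group,
                    measurement=(b == layout.measured_block),
                )
            )
    return rois


def build_outer_rois(
    region: tuple[float, float, float, float],
    edge_unit: float = 1.0,
    ring_depth: float = 0.5,
) -> list[ROI]:
    """Closed ring of ground-sampling rectangles just outside ``region``.

    Corner squares are ``ring_depth`` square and sit diagonally off the four
    region corners. Each side is divided evenly into
    ``max(1, ceil((L - 2 * ring_depth) / edge_unit))`` rectangles of depth
    ``ring_depth`` spanning the full side, so the ring is gap-free and the
    piece length is approximately ``edge_unit``.
    """
    xmin, ymin, xmax, ymax = region
    w, l = xmax - xmin, ymax - ymin
    if w <= 0 or l <= 0 or edge_unit <= 0 or ring_depth <= 0:
        raise ValueError("region, edge_unit and ring_depth must be positive")
    d = ring_depth
    rois = [
        ROI(f"corner{k}", "outer", rect)
        for k, rect in enumerate(
            [
                (xmin - d, ymin - d, xmin, ymin),
                (xmax, ymin - d, xmax + d, ymin),
                (xmax, ymax, xmax + d, ymax + d),
                (xmin - d, ymax, xmin, ymax + d),
            ]
        )
    ]

    def side_pieces(lo: float, hi: float) -> list[tuple[float, float]]:
        span = hi - lo
        n = max(1, math.ceil((span - 2 * d) / edge_unit - 1e-9))
        cuts = np.linspace(lo, hi, n + 1)
        return list(zip(cuts[:-1], cuts[1:]))

    for k, (a, b) in enumerate(side_pieces(xmin, xmax)):
        rois.append(ROI(f"south{k}", "outer", (a, ymin - d, b, ymin)))
        rois.append(ROI(f"north{k}", "outer", (a, ymax, b, ymax + d)))
    for k, (a, b) in enumerate(side_pieces(ymin, ymax)):
        rois.append(ROI(f"west{k}", "outer", (xmin - d, a, xmin, b)))
        rois.append(ROI(f"east{k}", "outer", (xmax, a, xmax + d, b)))
    return rois


def _index_range(lo: float, hi: float, origin: float, step: float, n: int) -> tuple[int, int]:
    """Indices i with center origin + (i+0.5)*step in [lo, hi), clipped to [0, n)."""
    first = math.ceil((lo - origin) / step - 0.5)
    last = math.ceil((hi - origin) / step - 0.5)  # exclusive
    return max(first, 0), min(last, n)


def extract_pixels(raster: RasterGrid, roi: ROI) -> PixelSample:
    """Values of all pixels whose centers fall inside the ROI rectangle.

    Nodata pixels are excluded from ``values`` and reported via
    ``nodata_fraction``. Raises :class:`EmptyROIError` if no pixel center is
    inside, :class:`DegradedROIError` if the nodata fraction exceeds 50%.
    """
    xmin, ymin, xmax, ymax = roi.rect
    ny, nx = raster.shape
    j0, j1 = _index_range(xmin, xmax, raster.origin[0], raster.pixel_size, nx)
    i0, i1 = _index_range(ymin, ymax, raster.origin[1], raster.pixel_size, ny)
    if j0 >= j1 or i0 >= i1:
        raise EmptyROIError(f"no pixel centers inside ROI {roi.id} {roi.rect}")
    block = raster.values[i0:i1, j0:j1]
    valid = block[block != raster.nodata]
    n_total = block.size
    nodata_fraction = 1.0 - valid.size / n_total
    if nodata_fraction > NODATA_TOLERANCE:
        raise DegradedROIError(
            f"ROI {roi.id}: {nodata_fraction:.0%} nodata exceeds "
            f"{NODATA_TOLERANCE:.0%} tolerance"
        )
    return PixelSample(values=valid.ravel(), nodata_fraction=nodata_fraction, n_total=n_total)


def percentile(values: Sequence[float] | np.ndarray, q: float) -> float:
    """Linear-interpolation percentile of a non-empty sample."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of an empty sample is undefined")
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"percentile rank must be in [0, 100], got {q}")
    return float(np.percentile(values, q))


def median_center(raster: RasterGrid, roi: ROI) -> tuple[float, float, float]:
    """(x, y, z) ground sample point of an ROI: rectangle centroid and the
    median elevation of its pixels."""
    sample = extract_pixels(raster, roi)
    x, y = roi.centroid
    return (x, y, percentile(sample.values, 50.0))


# ---- vector / table I/O ---------------------------------------------------


def rois_to_geojson(rois: Iterable[ROI]) -> dict:
    features = []
    for roi in rois:
        xmin, ymin, xmax, ymax = roi.rect
        ring = [[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax], [xmin, ymin]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "id": roi.id,
                    "kind": roi.kind,
                    "group": roi.group,
                    "measurement": roi.measurement,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(rois: Iterable[ROI], path) -> None:
    with open(path, "w") as fh:
        json.dump(rois_to_geojson(rois), fh)


def read_geojson(path) -> list[ROI]:
    with open(path) as fh:
        collection = json.load(fh)
    rois = []
    for feat in collection["features"]:
        ring = feat["geometry"]["coordinates"][0]
        xs = [p[0] for p in ring]
        ys = [p[1] for p in ring]
        props = feat["properties"]
        rois.append(
            ROI(
                id=props["id"],
                kind=props["kind"],
                rect=(min(xs), min(ys), max(xs), max(ys)),
                group=props.get("group"),
                measurement=bool(props.get("measurement", False)),
            )
        )
    return rois


def write_roi_centroids(rois: Iterable[ROI], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "kind", "x", "y"])
        for roi in rois:
            x, y = roi.centroid
            writer.writerow([roi.id, roi.kind, f"{x:.6f}", f"{y:.6f}"])
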