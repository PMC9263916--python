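"""The three ground-altitude methods that turn a DSM into crop height.

* **M1 — off-season differencing.** The DSM of a bare-ground (pre-germination)
  flight serves as the DTM and is subtracted from the on-season DSM. Pairs
  are matched by acquisition condition and repetition index. Because the two
  flights carry independent vertical datum errors, the resulting crop height
  model (CHM) is shifted by the *difference* of the two datums — the reason
  this method needs ground control points.
* **M2 — within-ROI percentiles.** Inside each plant ROI the 2nd percentile
  estimates the soil altitude and the 98th percentile the plant apex; their
  difference is the SfM plant height. Needs visible soil inside the ROI.
* **M3 — polynomial DTM interpolation.** The median altitude of each
  bare-ground rectangle in the ring around the field gives one (x, y, z)
  sample; a degree-``n`` polynomial surface fitted to those samples is the
  DTM, and CHM = DSM − DTM. Any constant datum error is absorbed by the
  surface's constant term, so M2 and M3 are datum-invariant while M1 is not.

The polynomial degree is chosen on a calibration field by maximizing the
mean (over flight repetitions) Pearson correlation between measured and
SfM-derived heights; ties break toward the lower degree.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .raster import RasterGrid
from .roi import ROI, extract_pixels, median_center, percentile
from .surface import PolySurface, fit_polynomial_dtm, surface_to_raster

__all__ = [
    "method_m1",
    "method_m2",
    "method_m3",
    "fit_ground_surface",
    "select_degree",
    "chm_roi_height",
]


def method_m1(on_season: RasterGrid, off_season: RasterGrid) -> RasterGrid:
    """CHM = on-season DSM − off-season DSM (grids must align; nodata
    propagates from either input)."""
    return on_season.subtract(off_season)


def method_m2(dsm: RasterGrid, roi: ROI, q_high: float = 98.0, q_low: float = 2.0) -> float:
    """Plant height of one ROI as the spread between its apex and soil
    percentiles on the raw DSM."""
    sample = extract_pixels(dsm, roi)
    return percentile(sample.values, q_high) - percentile(sample.values, q_low)


def fit_ground_surface(
    dsm: RasterGrid, outer_rois: Sequence[ROI], degree: int
) -> tuple[PolySurface, np.ndarray]:
    """Fit the ground surface to the outer-ring samples of a DSM.

    Returns the fitted surface and its residuals at the sample points
    (z − surface), in ring order.
    """
    points = np.array([median_center(dsm, roi) for roi in outer_rois])
    surface = fit_polynomial_dtm(points, degree)
    residuals = points[:, 2] - surface(points[:, 0], points[:, 1])
    return surface, residuals


def method_m3(dsm: RasterGrid, outer_rois: Sequence[ROI], degree: int) -> RasterGrid:
    """CHM = DSM − polynomial DTM interpolated from the outer ground ring."""
    surface, _ = fit_ground_surface(dsm, outer_rois, degree)
    return dsm.subtract(surface_to_raster(surface, dsm))


def chm_roi_height(chm: RasterGrid, roi: ROI, q: float = 98.0) -> float:
    """Plot-level SfM plant height: the q-th percentile of a CHM inside an
    ROI (98th by default, which ignores noise touching < 2% of the pixels)."""
    sample = extract_pixels(chm, roi)
    return percentile(sample.values, q)


def select_degree(correlation_by_degree: Mapping[int, float]) -> int:
    """Degree with the strongest mean correlation; ties toward the lowest.

    ``correlation_by_degree`` maps candidate degree -> mean Pearson r over
    flight repetitions.
    """
    if not correlation_by_degree:
        raise ValueError("no candidate degrees supplied")
    best = max(sorted(correlation_by_degree), key=lambda d: (correlation_by_degree[d], -d))
    return int(best)
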