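"""Synthetic UAV-SfM scenes: true plant heights and per-flight DSM rasters.

The simulator replaces the photogrammetric reconstruction with an additive
per-pixel composition that carries the same statistical structure the
downstream analysis has to cope with::

    DSM(x, y) = ground(x, y)            # polynomial terrain + soil roughness
              + dome(x, y)              # central SfM "doming" bulge
              + datum_offset            # per-flight vertical datum error
              + canopy(x, y)            # plants, on-season flights only
              + pixel_noise + blobs     # reconstruction noise

* **ground** is a low-degree polynomial (the macroscopic tilt and curvature
  of the field) plus a smooth sinusoidal roughness field that is *not*
  polynomial — real soil unevenness that no finite-degree ground model can
  absorb. The roughness belongs to the true terrain, so it is identical in
  every flight.
* **dome** is a radially symmetric paraboloid centered on the analysis
  region. It is an artifact of every SfM reconstruction, so it appears in
  off-season flights too, with a small per-flight amplitude jitter; diagonal
  camera angles (-60 deg) suppress it relative to nadir (-90 deg).
* **datum_offset** is a single vertical shift drawn per flight. RTK shrinks
  its scale by :data:`RTK_OFFSET_FACTOR`; the GCP flag zeroes the realized
  offset (ground control anchors the datum).
* **canopy** renders each plant as a disc with a flat apex core and a linear
  taper to the ground at the rim. The apex is attenuated by a systematic
  ``apex_shrinkage`` (SfM underestimates thin plant tops) plus a per-plant,
  per-flight jitter. Between plants, inside the planted plots, the soil is
  only partially reconstructed: each no-canopy pixel shows true ground with
  a camera-angle-dependent probability (nadir sees soil between rows;
  diagonal views occlude it) and is otherwise filled with an interpolated
  canopy-like surface, the way SfM hole-filling bridges hidden ground.

Everything is drawn from a generator seeded by the flight scenario, so
identical specs and seeds give bit-identical rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import SeasonConflictError
from .field import FieldLayout
from .raster import RasterGrid
from .surface import PolySurface, evaluate_surface

__all__ = [
    "TerrainSpec",
    "CanopySpec",
    "FlightScenario",
    "NoiseSpec",
    "AngleEffects",
    "TrueHeights",
    "ANGLE_EFFECTS",
    "RTK_OFFSET_FACTOR",
    "generate_true_heights",
    "render_dsm",
]


@dataclass(frozen=True)
class AngleEffects:
    """Scalar knobs through which the camera angle acts on a reconstruction."""

    doming: float  # multiplier on the doming amplitude
    soil_visibility: float  # multiplier on the visible-soil fraction
    apex_jitter: float  # multiplier on the per-flight apex jitter


#: -60 deg (diagonal) suppresses the dome and occludes soil between plants
#: but captures plant structure a little better; -90 deg (nadir) is the
#: opposite on all three counts.
ANGLE_EFFECTS: dict[int, AngleEffects] = {
    -60: AngleEffects(doming=0.25, soil_visibility=0.25, apex_jitter=0.8),
    -90: AngleEffects(doming=1.0, soil_visibility=1.0, apex_jitter=1.2),
}

#: vertical datum scatter with RTK relative to plain GNSS
RTK_OFFSET_FACTOR = 0.06

_SEASON_CODES = {"pre_germination": 0, "on_season": 1}


@dataclass(frozen=True)
class TerrainSpec:
    """True ground plus the reconstruction distortions shared by all flights."""

    true_dtm: PolySurface
    doming_amplitude: float = 0.08  # m, at the region center, nadir camera
    doming_radius: Optional[float] = None  # m; default: half the region diagonal
    doming_jitter_frac: float = 0.1  # per-flight sd as a fraction of amplitude
    per_flight_vertical_offset_sd: float = 0.5  # m, without RTK
    roughness_amplitude: float = 0.02  # m RMS-ish soil unevenness
    roughness_wavelength: float = 8.0  # m, dominant scale of the unevenness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doming_amplitude < 0 or self.per_flight_vertical_offset_sd < 0:
            raise ValueError("doming amplitude and offset sd must be >= 0")
        if self.roughness_amplitude < 0:
            raise ValueError("roughness amplitude must be >= 0")

    def _roughness_terms(self, n_terms: int = 6):
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7]))
        theta = rng.uniform(0, 2 * np.pi, n_terms)
        wavelength = self.roughness_wavelength * rng.uniform(0.5, 2.0, n_terms)
        phase = rng.uniform(0, 2 * np.pi, n_terms)
        amp = self.roughness_amplitude * np.sqrt(2.0 / n_terms) * np.ones(n_terms)
        return theta, wavelength, phase, amp

    def ground_elevation(self, x, y):
        """True bare-ground elevation: polynomial macro-relief + roughness."""
        z = evaluate_surface(self.true_dtm, x, y)
        if self.roughness_amplitude > 0:
            x = np.asarray(x, dtype=float)
            y = np.asarray(y, dtype=float)
            for th, lam, ph, a in zip(*self._roughness_terms()):
                kx, ky = np.cos(th) / lam, np.sin(th) / lam
                z = z + a * np.sin(2 * np.pi * (kx * x + ky * y) + ph)
        return z


@dataclass(frozen=True)
class CanopySpec:
    """Height distribution and rendering geometry of one growth stage."""

    stage: str  # "vegetative" | "reproductive"
    height_mean: float
    height_sd: float
    height_min: float
    height_max: float
    apex_shrinkage: float  # m, systematic SfM underestimation of the apex
    soil_visible_fraction: float  # base probability that a soil gap shows ground
    plant_footprint_radius: float  # m
    plant_height_jitter_sd: float = 0.02  # m, plant-to-plant within a row
    apex_flight_jitter_sd: float = 0.05  # m, per plant per flight
    variety_fraction: float = 0.7  # share of height variance between plots
    core_fraction: float = 0.5  # flat apex core radius / footprint radius
    occlusion_fill_fraction: float = 0.75  # occluded soil fill / local canopy height
    occlusion_reach: float = 0.5  # m, dilation window for the occlusion fill
    soil_patch_scale: float = 0.5  # m, correlation length of visible-soil patches
    fill_noise_sd: float = 0.3  # relative noise on the occlusion fill level
    fill_noise_scale: float = 2.0  # m, correlation length of the fill noise

    def __post_init__(self) -> None:
        if not 0.0 <= self.soil_visible_fraction <= 1.0:
            raise ValueError("soil_visible_fraction must be in [0, 1]")
        if not self.height_min <= self.height_mean <= self.height_max:
            raise ValueError("need height_min <= height_mean <= height_max")
        if self.apex_shrinkage < 0:
            raise ValueError("apex_shrinkage must be >= 0")
        if not 0.0 < self.variety_fraction <= 1.0:
            raise ValueError("variety_fraction must be in (0, 1]")

    @classmethod
    def vegetative(cls, **overrides) -> "CanopySpec":
        """Maize a few weeks after emergence (heights around 0.9 m)."""
        defaults = dict(
            stage="vegetative",
            height_mean=0.898,
            height_sd=0.102,
            height_min=0.632,
            height_max=1.190,
            apex_shrinkage=0.08,
            soil_visible_fraction=0.9,
            plant_footprint_radius=0.12,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def reproductive(cls, **overrides) -> "CanopySpec":
        """Tasseling maize (heights around 2.7 m, canopy closed over the soil)."""
        defaults = dict(
            stage="reproductive",
            height_mean=2.68,
            height_sd=0.181,
            height_min=2.18,
            height_max=3.14,
            apex_shrinkage=0.23,
            soil_visible_fraction=0.05,
            plant_footprint_radius=0.30,
            apex_flight_jitter_sd=0.09,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class FlightScenario:
    """One UAV acquisition: the knobs that shape its reconstruction."""

    camera_angle: int = -60  # degrees, -60 (diagonal) or -90 (nadir)
    rtk: bool = False
    gcp: bool = False
    season: str = "on_season"  # "pre_germination" | "on_season"
    repetition: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.camera_angle not in ANGLE_EFFECTS:
            raise ValueError(f"camera_angle must be one of {sorted(ANGLE_EFFECTS)}")
        if self.season not in _SEASON_CODES:
            raise ValueError(f"unknown season {self.season!r}")
        if self.repetition < 1:
            raise ValueError("repetition index starts at 1")

    def rng(self) -> np.random.Generator:
        """Deterministic per-flight stream; GCP on/off shares the stream so a
        GCP-corrected raster differs only by the removed datum offset."""
        key = (
            _SEASON_CODES[self.season],
            self.repetition,
            abs(self.camera_angle),
            int(self.rtk),
        )
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=key))


@dataclass(frozen=True)
class NoiseSpec:
    """Reconstruction noise: per-pixel scatter plus small high blobs."""

    blob_count_per_raster: int = 5
    blob_max_pixels: int = 30
    blob_height: float = 1.5  # m above the surface
    pixel_noise_sd: float = 0.015  # m

    def __post_init__(self) -> None:
        if self.blob_max_pixels < 1:
            raise ValueError("blob_max_pixels must be >= 1")
        if self.pixel_noise_sd < 0 or self.blob_height < 0 or self.blob_count_per_raster < 0:
            raise ValueError("noise magnitudes must be >= 0")

    #: largest observed blob footprint: ~30 px at the ~1.6 cm survey GSD
    BLOB_MAX_AREA_M2 = 30 * 0.016**2

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(blob_count_per_raster=0, blob_max_pixels=1, blob_height=0.0, pixel_noise_sd=0.0)

    @classmethod
    def for_pixel_size(cls, pixel_size: float, **overrides) -> "NoiseSpec":
        """Noise with the observed *physical* blob footprint expressed at the
        rendering resolution, so blobs stay below the 2%-of-ROI threshold the
        98th percentile is designed to ignore."""
        max_px = max(1, round(cls.BLOB_MAX_AREA_M2 / pixel_size**2))
        defaults = dict(blob_max_pixels=max_px)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class TrueHeights:
    """Ground-truth heights for one field and stage.

    ``rows`` has one record per planting row (all rows, measured or not) with
    the row-level true height; measured rows carry a spatial group and
    ``ph_measured``, the mean ruler height of the five measured plants.
    ``plant_heights`` aligns with ``FieldLayout.all_plant_positions()``.
    """

    rows: pd.DataFrame
    plant_heights: np.ndarray

    def measured_table(self) -> pd.DataFrame:
        return self.rows[self.rows["measured"]].reset_index(drop=True)


def generate_true_heights(layout: FieldLayout, canopy: CanopySpec, seed: int) -> TrueHeights:
    """Draw true plant heights: plot (variety) effect + row effect + per-plant
    jitter, clipped to the stage's [height_min, height_max] range."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    sd_variety = canopy.height_sd * math.sqrt(canopy.variety_fraction)
    sd_row = canopy.height_sd * math.sqrt(1.0 - canopy.variety_fraction)
    variety = rng.normal(0.0, sd_variety, layout.n_plots)
    row_eff = rng.normal(0.0, sd_row, (layout.n_plots, layout.rows_per_plot))
    row_ph = np.clip(
        canopy.height_mean + variety[:, None] + row_eff, canopy.height_min, canopy.height_max
    )
    plant_jitter = rng.normal(
        0.0,
        canopy.plant_height_jitter_sd,
        (layout.n_plots, layout.rows_per_plot, layout.plants_per_row),
    )
    plant_h = np.clip(row_ph[:, :, None] + plant_jitter, canopy.height_min, canopy.height_max)

    measured_idx = layout.measured_plant_indices()
    group_by_key = {(r.plot, r.row_index): r.group for r in layout.measured_rows()}
    records = []
    for plot in range(layout.n_plots):
        for r in range(layout.rows_per_plot):
            measured = (plot, r) in group_by_key
            records.append(
                {
                    "row_id": f"P{plot:03d}R{r}",
                    "plot": plot,
                    "row_index": r,
                    "measured": measured,
                    "group": group_by_key.get((plot, r), 0),
                    "true_ph": row_ph[plot, r],
                    "ph_measured": float(plant_h[plot, r, measured_idx].mean())
                    if measured
                    else np.nan,
                }
            )
    return TrueHeights(rows=pd.DataFrame.from_records(records), plant_heights=plant_h.ravel())


def _smooth_field(rng: np.random.Generator, shape: tuple, sigma_px: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length sigma_px."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(sigma_px, 1e-6))
    sd = field.std()
    return field / sd if sd > 0 else field


def _planted_mask(layout: FieldLayout, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Boolean grid mask of pixels whose centers fall inside any plot."""
    mask = np.zeros((ys.size, xs.size), dtype=bool)
    for plot in range(layout.n_plots):
        x0, y0 = layout.plot_origin(plot)
        j0, j1 = np.searchsorted(xs, [x0, x0 + layout.plot_width])
        i0, i1 = np.searchsorted(ys, [y0, y0 + layout.plot_length])
        mask[i0:i1, j0:j1] = True
    return mask


def _inject_blobs(values: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> None:
    """Raise small connected components by blob_height (in place)."""
    ny, nx = values.shape
    for _ in range(noise.blob_count_per_raster):
        size = int(rng.integers(1, noise.blob_max_pixels + 1))
        i, j = int(rng.integers(ny)), int(rng.integers(nx))
        pixels = {(i, j)}
        while len(pixels) < size:
            ci, cj = list(pixels)[int(rng.integers(len(pixels)))]
            di, dj = [(1, 0), (-1, 0), (0, 1), (0, -1)][int(rng.integers(4))]
            ni_, nj_ = ci + di, cj + dj
            if 0 <= ni_ < ny and 0 <= nj_ < nx:
                pixels.add((ni_, nj_))
        for pi, pj in pixels:
            values[pi, pj] += noise.blob_height


def render_dsm(
    layout: FieldLayout,
    terrain: TerrainSpec,
    canopy: Optional[CanopySpec],
    flight: FlightScenario,
    noise: NoiseSpec,
    pixel_size: float,
    heights: Optional[TrueHeights] = None,
    margin: float = 2.0,
    datum_offset: Optional[float] = None,
) -> RasterGrid:
    """Render one flight's DSM over the analysis region plus ``margin``.

    ``heights`` fixes the true plant heights (shared across flights of the
    same stage); if omitted they are generated from ``terrain.seed``.
    ``datum_offset`` overrides the random per-flight datum error (useful for
    controlled experiments); the GCP flag zeroes the applied offset either
    way.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if canopy is not None and flight.season == "pre_germination":
        raise SeasonConflictError("a pre-germination flight cannot carry a canopy")

    xmin, ymin, xmax, ymax = layout.region
    x0, y0 = xmin - margin, ymin - margin
    nx = math.ceil((xmax - xmin + 2 * margin) / pixel_size)
    ny = math.ceil((ymax - ymin + 2 * margin) / pixel_size)
    xs = x0 + (np.arange(nx) + 0.5) * pixel_size
    ys = y0 + (np.arange(ny) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)

    Z = np.asarray(terrain.ground_elevation(X, Y), dtype=float).copy()
    rng = flight.rng()
    angle = ANGLE_EFFECTS[flight.camera_angle]

    # central doming bulge: paraboloid over the region, per-flight amplitude
    dome_jitter = rng.normal(0.0, terrain.doming_jitter_frac)
    amp = terrain.doming_amplitude * angle.doming * (1.0 + dome_jitter)
    if amp != 0.0:
        cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
        R = terrain.doming_radius
        if R is None:
            R = math.hypot(xmax - xmin, ymax - ymin) / 2.0
        Z += amp * (1.0 - ((X - cx) ** 2 + (Y - cy) ** 2) / R**2)

    # per-flight vertical datum error
    drawn = rng.normal(
        0.0,
        terrain.per_flight_vertical_offset_sd * (RTK_OFFSET_FACTOR if flight.rtk else 1.0),
    )
    offset = drawn if datum_offset is None else float(datum_offset)
    if flight.gcp:
        offset = 0.0
    Z += offset

    if canopy is not None and flight.season == "on_season":
        if heights is None:
            heights = generate_true_heights(layout, canopy, terrain.seed)
        positions = layout.all_plant_positions()
        apex_jitter = rng.normal(
            0.0, canopy.apex_flight_jitter_sd * angle.apex_jitter, len(positions)
        )
        C = np.zeros_like(Z)
        r = canopy.plant_footprint_radius
        core = canopy.core_fraction * r
        half = int(math.ceil(r / pixel_size)) + 1
        for (px, py), h, jit in zip(positions, heights.plant_heights, apex_jitter):
            h_eff = h - canopy.apex_shrinkage + jit
            if h_eff <= 0:
                continue
            jc = int((px - x0) / pixel_size)
            ic = int((py - y0) / pixel_size)
            i0s, i1s = max(ic - half, 0), min(ic + half + 1, ny)
            j0s, j1s = max(jc - half, 0), min(jc + half + 1, nx)
            if i0s >= i1s or j0s >= j1s:
                continue
            d = np.hypot(
                xs[j0s:j1s][None, :] - px, ys[i0s:i1s][:, None] - py
            )
            taper = np.clip((r - d) / max(r - core, 1e-12), 0.0, 1.0)
            np.maximum(C[i0s:i1s, j0s:j1s], h_eff * taper, out=C[i0s:i1s, j0s:j1s])
        # partial soil reconstruction between plants: inside the planted
        # plots, ground is visible only in spatially clumped patches (a
        # pixel is visible with probability soil_frac, correlated over
        # soil_patch_scale); everywhere else the reconstruction bridges the
        # hidden ground with a noisy canopy-like fill, the way SfM
        # hole-filling interpolates over occlusions
        soil_frac = min(canopy.soil_visible_fraction * angle.soil_visibility, 1.0)
        planted = _planted_mask(layout, xs, ys)
        if soil_frac < 1.0 and canopy.occlusion_fill_fraction > 0:
            k = max(1, int(round(2 * canopy.occlusion_reach / pixel_size)) | 1)
            fill_level = ndimage.maximum_filter(C, size=k)
            patch = _smooth_field(rng, Z.shape, canopy.soil_patch_scale / pixel_size)
            visible = patch > stats.norm.isf(soil_frac) if soil_frac > 0 else np.zeros_like(planted)
            fill_noise = _smooth_field(rng, Z.shape, canopy.fill_noise_scale / pixel_size)
            # fill stays strictly below the local apexes so the 98th
            # percentile always reads the plants, never the bridging surface
            rel = np.clip(
                canopy.occlusion_fill_fraction * (1.0 + canopy.fill_noise_sd * fill_noise),
                0.0,
                0.92,
            )
            fill = rel * fill_level
            occluded = planted & ~visible
            C[occluded] = np.maximum(C[occluded], fill[occluded])
        Z += C

    if noise.pixel_noise_sd > 0:
        Z += rng.normal(0.0, noise.pixel_noise_sd, Z.shape)
    if noise.blob_count_per_raster > 0 and noise.blob_height > 0:
        _inject_blobs(Z, noise, rng)

    return RasterGrid(Z, origin=(x0, y0), pixel_size=pixel_size)
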