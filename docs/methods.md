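# Methods

`uavheight` implements plot-level plant-height (PH) estimation from UAV
structure-from-motion (SfM) elevation rasters, together with a synthetic
scene generator that stands in for the photogrammetric reconstruction. This
note documents the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The estimation problem

An on-season digital surface model (DSM) contains ground elevation plus
crop height. Extracting PH requires a ground altitude (GA) estimate, and the
package implements the three standard routes:

* **M1 — off-season differencing.** A bare-ground (pre-germination) DSM is
  used as the digital terrain model (DTM): CHM = DSM_on − DSM_off, pairing
  flights by acquisition condition and repetition. Because each SfM
  reconstruction carries its own vertical datum error, the CHM inherits the
  *difference* of the two datums; M1 is therefore datum-sensitive and in
  practice needs ground control points (GCPs).
* **M2 — within-ROI percentiles.** Inside each plant rectangle the 2nd
  percentile of the DSM estimates the soil altitude and the 98th percentile
  the plant apex; PH = p98 − p2. Valid only while soil is actually present
  in the reconstruction inside the rectangle.
* **M3 — polynomial DTM interpolation.** Bare ground is sampled in a ring of
  rectangles just outside the field (median elevation at the rectangle
  centroid), a bivariate polynomial surface

      z = Σ_{k=0..n} Σ_{i=0..k} a_ki x^(k−i) y^i

  is fitted by least squares and used as the DTM: CHM = DSM − DTM. A
  constant datum error is absorbed by a00, so M3 (like M2) is
  datum-invariant.

Plot-level PH_SfM is the 98th percentile of the CHM inside the measured-row
rectangle (~2,500 px at survey resolution): high enough to read the apex,
low enough that reconstruction-noise blobs of ≤ 30 adjacent pixels (< 2% of
the ROI) cannot move it by more than one inter-pixel elevation step.

## Polynomial surface numerics

Raw field coordinates (tens of meters) make the degree-3/4 monomial basis
numerically singular, so coordinates are centered and scaled to the sample
bounding box (≈ [−1, 1]) before solving; coefficients are stored in (k, i)
lexicographic order on the conditioned coordinates (the serialization order
is a package convention). Rank-deficient systems raise an error instead of
returning a minimum-norm solution: on a perfectly regular rectangular ring
the quartic (u²−u₀²)(v²−v₀²) vanishes at **every** sample point, so a
degree-4 fit to ring-only data is exactly degenerate — silent minimum-norm
output would be an arbitrary ground model. Degree selection (below) treats
such degrees as unusable.

The fitting degree is chosen on a calibration field by maximizing the mean
Pearson correlation between PH_measured and PH_SfM over flight repetitions,
ties broken toward the lower degree. On the default cubic-relief terrain
this selects degree 3, with degree ≤ 2 leaving structured residuals and
degree 4 rejected as degenerate.

**Discretization limit of M3.** The ring sample pairs the *median*
elevation of a rectangle with its *centroid*. For terrain curved within the
rectangle these disagree by O(curvature × size²), ≈ 1e-4 m for the default
synthetic terrain and 1 × 0.5 m rectangles. Noise-free CHM recovery is
therefore exact (≤ 1e-6 m) only when the terrain is linear within each ring
rectangle; on curved terrain it is sub-millimeter, not machine, accurate.
The test suite pins both regimes.

## Calibration and cross-flight validation

SfM underestimates thin plant tops, so PH_measured = a·PH_SfM + b is fitted
by OLS per training flight. Validation is deliberately pessimistic
("different targets and different flight"): the 168 row samples are split
into three spatially contiguous groups; a model trained on two groups of one
flight repetition is scored on the held-out group of a *different*
repetition. All ordered repetition pairs × hold-out groups give
n_reps·(n_reps−1)·n_groups sets (18 for three repetitions): each set trains
on 112 and validates on 56 samples. Validation R² uses the validation
partition's own mean and is not clipped below zero — a calibration carrying
a foreign datum offset scores arbitrarily negative, which is the failure
the scheme exists to expose. MAE, RMSE and MAPE (= mean(|error|/measured)
× 100) use their standard definitions. Condition tables are ranked by
validation R².

## The synthetic scene generator

The generator replaces photogrammetry with an additive per-pixel
composition whose terms mirror the error structure of real SfM products:

| component | default | rationale |
|---|---|---|
| terrain | cubic polynomial, ~1 m relief over 35.5 × 54 m, plus ~2 cm sinusoidal soil roughness (8 m scale) | macroscopic tilt/curvature a polynomial DTM can absorb; roughness no polynomial can |
| doming bulge | paraboloid, 8 cm amplitude at −90°, ×0.25 at −60°, 10% per-flight jitter | the central SfM dome; diagonal imaging suppresses it |
| datum offset | N(0, 0.5 m) per flight; ×0.06 with RTK (≈3 cm); zeroed by GCP | GNSS vertical uncertainty vs. RTK vs. surveyed control |
| plant rendering | disc footprint (r = 0.12 m vegetative / 0.30 m reproductive), flat apex core, linear taper; apex lowered by `apex_shrinkage` (0.08 / 0.23 m) plus per-plant-per-flight jitter (0.05 / 0.09 m, ×0.8 at −60°, ×1.2 at −90°) | systematic apex underestimation (negative bias) and flight-to-flight scatter; diagonal views capture plant structure slightly better |
| soil visibility | no-canopy pixels inside plots show ground in clumped patches (P = 0.9 vegetative / 0.05 reproductive, ×0.25 at −60°); occluded pixels take a noisy canopy-like fill (0.75 × local canopy max, ±30% smooth noise, capped below the apexes) | nadir sees inter-row soil; diagonal views and closed canopies do not; SfM hole-filling bridges hidden ground |
| noise | 1.5 cm per-pixel scatter plus ≤ 5 blobs of the observed physical footprint (≤ 77 cm² ≈ 30 px at 1.6 cm GSD, hence 3 px at the 5 cm render pixel) raised 1.5 m | observed reconstruction noise; keeping the *physical* blob size ensures blobs stay below the 2%-of-ROI threshold the 98th percentile ignores |

True heights are drawn per row as plot (variety) effect + row effect
(70/30 variance split) around the stage means (0.898 ± 0.102 m vegetative,
2.68 ± 0.181 m reproductive, clipped to the observed ranges), with 2 cm
plant-to-plant jitter; PH_measured is the mean of the five measured plants.
The field layout is the maize trial design: 84 (validation) or 42
(calibration) four-row plots of 18 plants at 0.75 × 0.18 m spacing
(7.41 plants/m²), middle two rows measured, rows split into three blocks.

The doming bulge is applied to *every* flight (including pre-germination),
since it is a property of each reconstruction, not of the crop; this is
what lets GCP-corrected off-season differencing perform on par with the
polynomial DTM, as observed in the field. Per-flight magnitudes of the
datum offsets are assumptions — no deposited per-flight deviation data
exist — chosen at the scale of GNSS (decimeters) and RTK (centimeters)
vertical errors.

Everything is drawn from generators seeded by the flight scenario, so a
given configuration is bit-reproducible; the GCP variant of a flight shares
its reconstruction stream and differs only by the removed datum offset.

## Problem sizes and runtime

Default rasters use a 5 cm pixel (≈ 790 × 1160 cells for the field plus a
2 m margin), three flight repetitions per acquisition condition, and the
full 2 × 2 × 2 × 3 condition grid; a complete two-field study (degree
selection plus 24-condition comparison over both stages) renders ~100
flights and runs in under two minutes on one CPU. Raster products are
float32 TIFF, which quantizes ~100 m elevations at the 1e-5 m level.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate that the *analysis* behaves as the field study
found: off-season differencing collapses under inter-flight datum errors
unless GCPs (or, partially, RTK) anchor the datum; percentile ground
extraction fails exactly where soil leaves the reconstruction; the
polynomial DTM is datum-invariant and recovers heights wherever a ring of
bare ground is visible; and a cubic surface is the right ground model for
terrain with genuine cubic relief. The generator does not model
photogrammetric imaging, occlusion geometry, wind or illumination, weeds in
the ground ring, or spatially correlated GNSS drift; absolute metric values
from synthetic scenes (e.g. validation R² ≈ 0.85–0.93 at the defaults) are
therefore not predictions of field performance, only of its structure.

## Known limitations

* Axis-aligned rectangles only; ROIs are defined in field coordinates, not
  digitized on imagery.
* No geodetic CRS handling — coordinates are local planar meters.
* M3's ring sampling has the median-at-centroid curvature bias discussed
  above; for strongly curved terrain, smaller ring rectangles (or a mean
  with explicit bias correction) would be required.
* ROIs with more than 50% nodata are rejected rather than repaired.
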