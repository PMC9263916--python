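# uavheight

Plot-level plant height from UAV structure-from-motion (SfM) elevation
rasters, for field phenotypers and agronomists comparing acquisition
strategies (camera angle, RTK positioning, ground control points) and
ground-altitude methods before committing to a survey protocol.

An on-season digital surface model (DSM) is ground elevation plus crop.
`uavheight` implements the three standard ways to remove the ground and
obtain a crop height model (CHM):

* **M1** — subtract an off-season (bare ground) DSM: `CHM = DSM_on − DSM_off`;
* **M2** — within each plant rectangle, read soil and apex from the DSM's
  2nd and 98th percentiles: `PH = p98 − p2`;
* **M3** — sample bare ground in a ring of rectangles around the field
  (median elevation at each rectangle centroid), fit the bivariate
  polynomial surface `z = Σ_{k=0..n} Σ_{i=0..k} a_ki x^(k−i) y^i` by least
  squares, and subtract it as the DTM.

Plot-level `PH_SfM` is the 98th percentile of the CHM inside a measured
row's rectangle. Because SfM shaves thin plant tops, `PH_SfM`
underestimates ruler measurements; a linear calibration
`PH_measured = a · PH_SfM + b` is fitted by OLS and validated with a
deliberately pessimistic **different-targets-and-different-flight**
cross-validation: train on two of three spatial groups from one flight,
validate on the held-out group of a *different* flight (18 sets for three
repetitions; 112 training / 56 validation samples each). Validation R² is
unclipped, so a calibration carrying a foreign flight's datum error scores
strongly negative — exactly the failure mode that separates the methods.

Because real SfM rasters of the original trial are not redistributable, the
package ships a synthetic scene generator that emulates their error
structure — tilted-plus-cubic terrain, soil roughness, the central SfM
"doming" bulge, per-flight vertical datum offsets (shrunk by RTK, zeroed by
GCPs), apex shrinkage, partial soil visibility and noise blobs — so the
entire analysis is reproducible and testable end to end. See
`docs/methods.md` for the model and every default.

## Worked example

Simulate a 24-plot maize field at the vegetative stage, fly it three times
at a −60° camera angle without RTK, and compare off-season differencing
(M1) and the polynomial DTM (M3) with and without GCP correction:

```python
from uavheight.pipeline import (ExperimentConfig, default_terrain,
                                simulate_stage_samples, evaluate_stage)
from uavheight.field import make_field_layout
from uavheight.simulate import CanopySpec, NoiseSpec

config = ExperimentConfig(
    layout=make_field_layout(n_plots=24, n_plot_cols=4,
                             region_width=18.0, region_length=26.0),
    terrain=default_terrain(seed=1),
    canopies={"vegetative": CanopySpec.vegetative()},
    noise=NoiseSpec.for_pixel_size(0.05),
    camera_angles=(-60,), rtk_options=(False,), gcp_options=(False, True),
    methods=("M1", "M3"), n_repetitions=3, pixel_size=0.05, seed=1)

samples = simulate_stage_samples(config, "vegetative")
result = evaluate_stage(config, samples)
print(result.table[["camera_angle", "rtk", "gcp", "method", "r", "bias",
                    "r2_train", "r2_val", "mae"]].round(3).to_string(index=False))
```

```
 camera_angle rtk gcp method     r   bias  r2_train   r2_val   mae
          -60   -   +     M1 0.916 -0.024     0.839    0.795 0.030
          -60   -   +     M3 0.887 -0.019     0.789    0.706 0.038
          -60   -   -     M3 0.887 -0.019     0.789    0.706 0.038
          -60   -   -     M1 0.916 -0.151     0.839 -174.109 1.060
```

Reading the table: `r` is the within-flight correlation between measured
and SfM height (means over the three repetitions), `bias` the mean of
`PH_SfM − PH_measured` in meters, and `r2_val`/`mae` the cross-flight
validation scores (means over the six validation sets here). All four
conditions correlate well within a flight, but M1 without ground control
(last row) collapses to R²_val = −174 with an MAE of over a meter: its
calibration absorbs the training flight's datum error and inherits a
different one at validation. The same M1 heights corrected with GCPs
(first row) validate at R²_val ≈ 0.80, and the polynomial DTM is identical
with and without GCPs because a constant datum shift is absorbed by the
surface's constant term.

The same pipeline is available from the shell: `uavheight simulate`,
`extract`, `calibrate`, `report`, and `uavheight replicate` for the full
two-field preset (degree selection on a 42-plot calibration field, then the
24-condition comparison — 2 camera angles × RTK on/off × GCP on/off ×
3 methods — on an 84-plot validation field at both growth stages).

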