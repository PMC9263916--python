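"""Ground-altitude methods M1/M2/M3 and polynomial degree selection."""

import numpy as np
import pytest

from uavheight.errors import GridAlignmentError
from uavheight.field import make_field_layout
from uavheight.methods import (
    chm_roi_height,
    fit_ground_surface,
    method_m1,
    method_m2,
    method_m3,
    select_degree,
)
from uavheight.raster import RasterGrid
from uavheight.roi import ROI, build_inner_rois, build_outer_rois
from uavheight.simulate import (
    CanopySpec,
    FlightScenario,
    NoiseSpec,
    TerrainSpec,
    generate_true_heights,
    render_dsm,
)
from uavheight.surface import PolySurface, surface_to_raster


def grid(values, origin=(0.0, 0.0), pixel=1.0):
    return RasterGrid(np.asarray(values, dtype=float), origin, pixel)


# ---------------------------------------------------------------------------
# M1


def test_m1_identical_flights_give_zero_chm():
    dsm = grid(np.random.default_rng(0).normal(100, 1, (8, 8)))
    assert np.allclose(method_m1(dsm, dsm).values, 0.0)


def test_m1_constant_growth():
    off = grid(np.full((5, 5), 100.0))
    on = grid(np.full((5, 5), 101.5))
    assert np.allclose(method_m1(on, off).values, 1.5)


def test_m1_rejects_mismatched_grids():
    with pytest.raises(GridAlignmentError):
        method_m1(grid(np.zeros((5, 5))), grid(np.zeros((6, 5))))


def test_m1_carries_interflight_datum_difference(small_layout, flat_terrain, no_noise, quiet_canopy):
    """Off-season datum offset delta leaks into the M1 height as -delta:
    the central reason this method needs ground control."""
    heights = generate_true_heights(small_layout, quiet_canopy, seed=0)
    on = render_dsm(
        small_layout, flat_terrain, quiet_canopy,
        FlightScenario(season="on_season", seed=3), no_noise, 0.05,
        heights=heights, datum_offset=0.0,
    )
    delta = 0.8
    off = render_dsm(
        small_layout, flat_terrain, None,
        FlightScenario(season="pre_germination", seed=3), no_noise, 0.05,
        datum_offset=delta,
    )
    chm = method_m1(on, off)
    bare = ~_canopy_mask(on)
    assert np.allclose(chm.values[bare], -delta, atol=1e-9)
    roi = next(r for r in build_inner_rois(small_layout) if r.measurement)
    truth = heights.measured_table().set_index("row_id")
    expected = truth.loc[roi.id.rsplit("B", 1)[0], "ph_measured"] - quiet_canopy.apex_shrinkage
    assert chm_roi_height(chm, roi) == pytest.approx(expected - delta, abs=1e-9)


def _canopy_mask(dsm):
    return dsm.values > 100.0 + 1e-9


# ---------------------------------------------------------------------------
# M2


def test_m2_constant_roi_is_zero():
    dsm = grid(np.full((10, 10), 12.0))
    assert method_m2(dsm, ROI("a", "inner", (0, 0, 10, 10))) == pytest.approx(0.0)


def test_m2_two_cluster_roi():
    values = np.concatenate([np.full(100, 10.0), np.full(100, 12.0)]).reshape(10, 20)
    dsm = grid(values)
    assert method_m2(dsm, ROI("a", "inner", (0, 0, 20, 10))) == pytest.approx(2.0)


def test_m2_collapses_when_soil_hidden():
    """With the soil fully occluded the 2nd percentile reads canopy fill,
    not ground, and the extracted height collapses toward zero — the
    diagonal-camera failure mode."""
    soil_levels = {}
    for frac in (1.0, 0.0):
        values = np.full(400, 10.9)  # canopy-bridged surface
        n_soil = int(200 * frac)
        if n_soil:
            values[:n_soil] = 10.0  # visible ground at 10 m
        dsm = grid(values.reshape(20, 20))
        soil_levels[frac] = method_m2(dsm, ROI("a", "inner", (0, 0, 20, 20)))
    assert soil_levels[1.0] == pytest.approx(0.9)
    assert soil_levels[0.0] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# M3


#: region whose ring pieces (1.05 m) and depth (0.5 m) sit exactly on the
#: 0.05 m pixel grid, so every ring rectangle holds a point-symmetric set of
#: pixel centers and the median elevation sits exactly at the centroid for
#: terrain that is linear within the rectangle
ALIGNED_REGION = (0.0, 0.0, 10.5, 14.7)


def outer_ring(region=(0.0, 0.0, 10.0, 15.0)):
    return build_outer_rois(region, edge_unit=1.0, ring_depth=0.5)


def _plane_raster(region, pixel=0.05, margin=1.0):
    surf = PolySurface(1, [100.0, 0.04, -0.02])
    x0, y0 = region[0] - margin, region[1] - margin
    nx = int(round((region[2] - region[0] + 2 * margin) / pixel))
    ny = int(round((region[3] - region[1] + 2 * margin) / pixel))
    like = RasterGrid(np.zeros((ny, nx)), (x0, y0), pixel)
    return surface_to_raster(surf, like)


def test_m3_plane_terrain_gives_zero_chm():
    dsm = _plane_raster(ALIGNED_REGION)
    chm = method_m3(dsm, outer_ring(ALIGNED_REGION), degree=1)
    assert np.max(np.abs(chm.values)) <= 1e-9


def test_m3_datum_invariance_vs_m1_sensitivity():
    """A constant datum shift leaves M3 (and M2) unchanged but shifts M1 by
    the inter-flight datum difference."""
    region = (0.0, 0.0, 10.0, 15.0)
    dsm = _plane_raster(region)
    shifted = RasterGrid(dsm.values + 3.0, dsm.origin, dsm.pixel_size)
    chm_a = method_m3(dsm, outer_ring(region), degree=1)
    chm_b = method_m3(shifted, outer_ring(region), degree=1)
    assert np.max(np.abs(chm_a.values - chm_b.values)) < 1e-8
    roi = ROI("mid", "inner", (4, 6, 6, 9))
    assert method_m2(shifted, roi) == pytest.approx(method_m2(dsm, roi), abs=1e-12)
    m1 = method_m1(shifted, dsm)
    assert np.allclose(m1.values, 3.0)


def _quiet_recovery_scene(terrain, pixel=0.05):
    layout = make_field_layout(
        n_plots=6, n_plot_cols=2,
        region_width=ALIGNED_REGION[2], region_length=ALIGNED_REGION[3],
    )
    canopy = CanopySpec.vegetative(
        plant_height_jitter_sd=0.0, apex_flight_jitter_sd=0.0, soil_visible_fraction=1.0
    )
    heights = generate_true_heights(layout, canopy, seed=terrain.seed)
    dsm = render_dsm(
        layout, terrain, canopy, FlightScenario(-90, season="on_season", seed=5),
        NoiseSpec.none(), pixel, heights=heights,
    )
    return layout, canopy, heights, dsm


def _recovery_errors(layout, canopy, heights, chm):
    truth = heights.measured_table().set_index("row_id")
    errors = []
    for roi in (r for r in build_inner_rois(layout) if r.measurement):
        ph = chm_roi_height(chm, roi)
        expected = truth.loc[roi.id.rsplit("B", 1)[0], "ph_measured"] - canopy.apex_shrinkage
        errors.append(ph - expected)
    return np.array(errors)


def test_m3_exact_recovery_on_linear_terrain():
    """Noise-free terrain that is linear within every ring rectangle, fit
    degree 3 >= terrain degree 1: every per-row 98th-percentile height
    equals true height - apex shrinkage to 1e-6 m."""
    terrain = TerrainSpec(
        true_dtm=PolySurface(1, [100.0, 0.3, -0.5], center=(5.25, 7.35), scale=(5.25, 7.35)),
        doming_amplitude=0.0, doming_jitter_frac=0.0,
        per_flight_vertical_offset_sd=0.0, roughness_amplitude=0.0, seed=2,
    )
    layout, canopy, heights, dsm = _quiet_recovery_scene(terrain)
    chm = method_m3(dsm, outer_ring(ALIGNED_REGION), degree=3)
    assert np.max(np.abs(_recovery_errors(layout, canopy, heights, chm))) <= 1e-6


def test_m3_recovery_on_curved_terrain_is_discretization_limited():
    """With curved (cubic + dome) terrain, pairing the median elevation with
    the rectangle centroid biases each ring sample by O(curvature * size^2);
    recovery is then accurate to sub-millimeter, not machine, precision."""
    terrain = TerrainSpec(
        true_dtm=PolySurface(
            3,
            [100.0, 0.3, -0.5, 0.1, -0.06, 0.09, 0.07, -0.05, 0.04, -0.06],
            center=(5.25, 7.35), scale=(5.25, 7.35),
        ),
        doming_amplitude=0.05, doming_jitter_frac=0.0,
        per_flight_vertical_offset_sd=0.0, roughness_amplitude=0.0, seed=2,
    )
    layout, canopy, heights, dsm = _quiet_recovery_scene(terrain)
    chm = method_m3(dsm, outer_ring(ALIGNED_REGION), degree=3)
    assert np.max(np.abs(_recovery_errors(layout, canopy, heights, chm))) <= 1e-3


def test_ring_fit_residuals_shrink_with_degree(no_noise, small_layout):
    """On tilted-plus-bulge terrain the outer-ring RMS residual is
    non-increasing through degrees 0 -> 1 -> 2 -> 3."""
    terrain = TerrainSpec(
        true_dtm=PolySurface(2, [100.0, 0.4, -0.6, 0.12, -0.05, 0.1],
                             center=(5.0, 7.5), scale=(5.0, 7.5)),
        doming_amplitude=0.08, doming_jitter_frac=0.0,
        per_flight_vertical_offset_sd=0.0, roughness_amplitude=0.01, seed=4,
    )
    dsm = render_dsm(
        small_layout, terrain, None, FlightScenario(-90, season="pre_germination", seed=5),
        no_noise, 0.05,
    )
    rms = []
    for degree in (0, 1, 2, 3):
        _, resid = fit_ground_surface(dsm, outer_ring(small_layout.region), degree)
        rms.append(float(np.sqrt(np.mean(resid**2))))
    assert all(a >= b - 1e-12 for a, b in zip(rms, rms[1:]))
    assert rms[2] < rms[0]


# ---------------------------------------------------------------------------
# degree selection


def test_select_degree_reported_means():
    means = {0: 0.469, 1: 0.776, 2: 0.832, 3: 0.839, 4: 0.153}
    assert select_degree(means) == 3


def test_select_degree_tie_breaks_low():
    assert select_degree({0: 0.5, 1: 0.5, 2: 0.5}) == 0


def test_select_degree_empty_raises():
    with pytest.raises(ValueError):
        select_degree({})
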