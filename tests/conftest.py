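import numpy as np
import pytest

from uavheight.field import make_field_layout
from uavheight.simulate import CanopySpec, NoiseSpec, TerrainSpec
from uavheight.surface import PolySurface


@pytest.fixture(scope="session")
def field2_layout():
    """The 84-plot validation-field layout (168 measured rows)."""
    return make_field_layout(n_plots=84)


@pytest.fixture(scope="session")
def field1_layout():
    """The 42-plot calibration-field layout (84 measured rows)."""
    return make_field_layout(n_plots=42)


@pytest.fixture(scope="session")
def small_layout():
    """A 6-plot field small enough for fast rendering."""
    return make_field_layout(
        n_plots=6, n_plot_cols=2, region_width=10.0, region_length=15.0
    )


@pytest.fixture
def flat_terrain():
    """Level ground at 100 m with every distortion switched off."""
    return TerrainSpec(
        true_dtm=PolySurface(0, [100.0]),
        doming_amplitude=0.0,
        doming_jitter_frac=0.0,
        per_flight_vertical_offset_sd=0.0,
        roughness_amplitude=0.0,
        seed=3,
    )


@pytest.fixture
def no_noise():
    return NoiseSpec.none()


@pytest.fixture
def quiet_canopy():
    """Vegetative canopy with all stochastic components and occlusion off:
    every rendered apex sits exactly at true height - apex_shrinkage."""
    return CanopySpec.vegetative(
        plant_height_jitter_sd=0.0,
        apex_flight_jitter_sd=0.0,
        soil_visible_fraction=1.0,
    )
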