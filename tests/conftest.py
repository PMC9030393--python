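import numpy as np
import pytest

from weldtherm.solver import DriveWaveform, GeometryConfig, SimulationConfig


@pytest.fixture
def small_geometry_config() -> GeometryConfig:
    """Coarse desk-scale grid (10 x 5 x 8 cells) for fast solver tests."""
    return GeometryConfig(
        slab_length_x=4e-3,
        slab_width_y=2e-3,
        tissue_thickness=0.958e-3,
        electrode_footprint=1.2e-3,
        electrode_thickness=0.48e-3,
        dx=0.4e-3,
        dy=0.4e-3,
        dz_target=0.24e-3,
        dz_electrode_target=0.24e-3,
    )


@pytest.fixture
def small_sim_config(small_geometry_config) -> SimulationConfig:
    return SimulationConfig(
        geometry=small_geometry_config,
        drive=DriveWaveform(amplitude=8.0),
        dt=0.05,
        end_time=1.0,
        h_air=10.0,
        h_sink=200.0,
    )


@pytest.fixture
def insulated_sim_config(small_geometry_config) -> SimulationConfig:
    return SimulationConfig(
        geometry=small_geometry_config,
        drive=DriveWaveform(amplitude=0.0),
        dt=0.05,
        end_time=1.0,
        h_air=0.0,
        h_sink=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
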