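import dataclasses

import pytest

from flukeprints.photogrammetry import CameraModel, FlightContext
from flukeprints.synthetic import SimulationConfig


@pytest.fixture
def tir_camera() -> CameraModel:
    return CameraModel("TIR", 640, 512, 800.0)


@pytest.fixture
def flight() -> FlightContext:
    return FlightContext(altitude_m=90.0)


@pytest.fixture
def zero_noise_cfg() -> SimulationConfig:
    """One adult whale at 1.4 m/s with a 4 s stroke period, no noise anywhere."""
    return SimulationConfig(
        seed=7,
        n_adults=1,
        n_calves=0,
        adult_length_sd=0.0,
        speed_range=(1.4, 1.4),
        tailbeat_freq_range=(0.25, 0.25),
        events_per_whale=1,
        prints_per_event=5,
    ).zero_noise()


@pytest.fixture
def small_noisy_cfg() -> SimulationConfig:
    return SimulationConfig(
        seed=3, n_adults=10, n_calves=3, events_per_whale=2, prints_per_event=4
    )


def replace_cfg(cfg: SimulationConfig, **kwargs) -> SimulationConfig:
    return dataclasses.replace(cfg, **kwargs)
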