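"""Run configuration: camera blocks, simulation settings, analysis switches.

Configuration lives in a YAML file with (all optional) sections:

.. code-block:: yaml

    simulation:
      seed: 1
      n_adults: 80
      n_calves: 12
      width_model: {slope: 0.9, adult_noise_sd: 0.15, calf_noise_sd: 0.35}
      lmm_params: {beta0: -0.30, beta1: 0.33, sigma_u: 0.075, sigma_e: 0.143}
      rgb_camera: {image_width: 3840, image_height: 2160, focal_length_px: 2000}
      tir_camera: {image_width: 640, image_height: 512, focal_length_px: 800}
    analysis:
      cv_folds: 10
      cv_seed: 0
      deming_lambda: 1.0
      pi_level: 0.95
      frame_stride: 1

Omitted keys fall back to the defaults baked into the dataclasses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidInputError
from .photogrammetry import CameraModel, FlightContext
from .synthetic import LmmParams, SimulationConfig, WidthModel

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cv_folds: int = 10
    cv_seed: int = 0
    deming_lambda: float = 1.0
    pi_level: float = 0.95
    frame_stride: int = 1

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise InvalidInputError("cv_folds must be >= 2")
        if not (0 < self.pi_level < 1):
            raise InvalidInputError("pi_level must be in (0, 1)")
        if self.deming_lambda <= 0:
            raise InvalidInputError("deming_lambda must be positive")
        if self.frame_stride < 1:
            raise InvalidInputError("frame_stride must be >= 1")

    @property
    def flight(self) -> FlightContext:
        return FlightContext(
            altitude_m=self.simulation.altitude,
            altitude_sd_m=self.simulation.altitude_sd,
        )


def _camera(block: dict, label: str) -> CameraModel:
    return CameraModel(
        sensor_label=block.get("sensor_label", label),
        image_width=int(block["image_width"]),
        image_height=int(block["image_height"]),
        focal_length_px=float(block["focal_length_px"]),
        principal_point=tuple(block["principal_point"])
        if "principal_point" in block
        else None,
        radial_distortion=tuple(block.get("radial_distortion", (0.0, 0.0, 0.0))),
    )


def _simulation(block: dict) -> SimulationConfig:
    kwargs = dict(block)
    if "width_model" in kwargs:
        kwargs["width_model"] = WidthModel(**kwargs["width_model"])
    if "lmm_params" in kwargs:
        kwargs["lmm_params"] = LmmParams(**kwargs["lmm_params"])
    for cam_key, label in (("rgb_camera", "RGB"), ("tir_camera", "TIR")):
        if cam_key in kwargs:
            kwargs[cam_key] = _camera(kwargs[cam_key], label)
    for key in (
        "calf_length_fraction_range",
        "speed_range",
        "tailbeat_freq_range",
        "emergence_offset_range",
    ):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(kwargs) - valid
    if unknown:
        raise InvalidInputError(f"unknown simulation keys: {sorted(unknown)}")
    return SimulationConfig(**kwargs)


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; ``seed`` overrides the file."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    sim_block = dict(raw.get("simulation", {}))
    if seed is not None:
        sim_block["seed"] = int(seed)
    analysis = dict(raw.get("analysis", {}))
    valid = {f.name for f in dataclasses.fields(RunConfig)} - {"simulation"}
    unknown = set(analysis) - valid
    if unknown:
        raise InvalidInputError(f"unknown analysis keys: {sorted(unknown)}")
    return RunConfig(simulation=_simulation(sim_block), **analysis)
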