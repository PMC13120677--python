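"""Pixel-to-world mapping for a nadir-pointing drone camera.

A gimbal-stabilised camera looking straight down at the sea surface maps
pixels to metres through a single scalar, the ground sample distance
(GSD = altitude / focal length in pixels).  Lengths between annotated
pixel landmarks are therefore Euclidean pixel distances scaled by the GSD,
after removal of radial lens distortion.  Oblique frames are rejected:
they do not have a uniform ground scale and are excluded from measurement.

Measurement accuracy is validated against a reference object of known
length (e.g. a research vessel) filmed under survey conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError, InvalidInputError

__all__ = [
    "CameraModel",
    "FlightContext",
    "ReferenceValidation",
    "undistort_point",
    "ground_sample_distance",
    "measure_length",
    "validate_reference",
    "world_to_pixel",
    "pixel_to_world",
]


@dataclass(frozen=True)
class CameraModel:
    """Intrinsic model of one of the two gimbal sensors.

    Parameters
    ----------
    sensor_label:
        ``"RGB"`` or ``"TIR"``.
    image_width, image_height:
        Sensor resolution in pixels.
    focal_length_px:
        Focal length expressed in pixels.
    principal_point:
        Optical centre ``(cx, cy)`` in pixels; defaults to the image centre.
    radial_distortion:
        Brown–Conrady radial coefficients ``(k1, k2, k3)`` with the pixel
        radius from the principal point as the distortion variable.
    """

    sensor_label: str
    image_width: int
    image_height: int
    focal_length_px: float
    principal_point: tuple[float, float] | None = None
    radial_distortion: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sensor_label not in ("RGB", "TIR"):
            raise InvalidInputError(f"unknown sensor label {self.sensor_label!r}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise InvalidInputError("image dimensions must be positive")
        if not (self.focal_length_px > 0):
            raise InvalidInputError("focal length must be positive")
        if self.principal_point is None:
            object.__setattr__(
                self,
                "principal_point",
                (self.image_width / 2.0, self.image_height / 2.0),
            )
        cx, cy = self.principal_point
        if not (0 <= cx <= self.image_width and 0 <= cy <= self.image_height):
            raise InvalidInputError("principal point outside image bounds")
        k = tuple(float(v) for v in self.radial_distortion)
        if len(k) > 3:
            raise InvalidInputError("at most three radial coefficients supported")
        object.__setattr__(self, "radial_distortion", k + (0.0,) * (3 - len(k)))


@dataclass(frozen=True)
class FlightContext:
    """Flight-level context for scaling: altitude above sea level in metres."""

    altitude_m: float
    altitude_sd_m: float = 0.0
    nadir: bool = True

    def __post_init__(self) -> None:
        if not (self.altitude_m > 0):
            raise InvalidInputError("altitude must be positive")
        if self.altitude_sd_m < 0:
            raise InvalidInputError("altitude SD must be non-negative")


@dataclass(frozen=True)
class ReferenceValidation:
    """Accuracy summary against a reference object of known length."""

    true_length_m: float
    measured_lengths_m: tuple[float, ...]
    mean_abs_error_m: float = field(init=False)
    rel_error: float = field(init=False)

    def __post_init__(self) -> None:
        meas = np.asarray(self.measured_lengths_m, dtype=float)
        mae = float(np.mean(np.abs(meas - self.true_length_m)))
        object.__setattr__(self, "mean_abs_error_m", mae)
        object.__setattr__(self, "rel_error", mae / self.true_length_m)


def _check_point(p: Sequence[float]) -> tuple[float, float]:
    x, y = float(p[0]), float(p[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise InvalidInputError(f"non-finite point coordinates {p!r}")
    return x, y


def undistort_point(p: Sequence[float], cam: CameraModel) -> tuple[float, float]:
    """Remove radial lens distortion from a pixel point.

    Applies the Brown–Conrady radial polynomial about the principal point,
    with the radius measured in pixels:

        p' = c + (p - c) * (1 + k1 r^2 + k2 r^4 + k3 r^6)

    The identity is returned when all coefficients are zero, and the
    principal point itself is always a fixed point.
    """
    x, y = _check_point(p)
    # Tolerate slight overshoot beyond the sensor (annotations near edges).
    margin_x, margin_y = 0.1 * cam.image_width, 0.1 * cam.image_height
    if not (-margin_x <= x <= cam.image_width + margin_x) or not (
        -margin_y <= y <= cam.image_height + margin_y
    ):
        raise InvalidInputError(f"point {p!r} far outside image bounds")
    cx, cy = cam.principal_point
    dx, dy = x - cx, y - cy
    r2 = dx * dx + dy * dy
    k1, k2, k3 = cam.radial_distortion
    factor = 1.0 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
    return (cx + dx * factor, cy + dy * factor)


def ground_sample_distance(cam: CameraModel, ctx: FlightContext) -> float:
    """Metres covered by one pixel on the sea surface at nadir.

    GSD = altitude / focal length (both expressing the same pinhole
    similar-triangle relation). Raises :class:`GeometryError` for
    non-nadir frames, which have no single ground scale.
    """
    if not ctx.nadir:
        raise GeometryError("ground scale is only defined for nadir frames")
    return ctx.altitude_m / cam.focal_length_px


def measure_length(
    p1: Sequence[float],
    p2: Sequence[float],
    cam: CameraModel,
    ctx: FlightContext,
) -> float:
    """Real-world distance in metres between two annotated pixel points."""
    gsd = ground_sample_distance(cam, ctx)
    x1, y1 = undistort_point(p1, cam)
    x2, y2 = undistort_point(p2, cam)
    return math.hypot(x2 - x1, y2 - y1) * gsd


def validate_reference(
    measurements: Sequence[float], true_length: float
) -> ReferenceValidation:
    """Quantify absolute and relative measurement error against a known length."""
    if len(measurements) == 0:
        raise InvalidInputError("at least one measurement is required")
    if not (true_length > 0):
        raise InvalidInputError("true length must be positive")
    meas = tuple(float(m) for m in measurements)
    if not all(math.isfinite(m) for m in meas):
        raise InvalidInputError("non-finite measurement")
    return ReferenceValidation(true_length_m=float(true_length), measured_lengths_m=meas)


def world_to_pixel(
    east_m: float,
    north_m: float,
    cam: CameraModel,
    altitude_m: float,
    anchor_e: float = 0.0,
    anchor_n: float = 0.0,
) -> tuple[float, float]:
    """Project a local east/north point (metres) into the image plane.

    Image x grows eastwards, image y grows southwards (top-left origin),
    for a north-aligned, nadir frame centred on ``(anchor_e, anchor_n)``.
    """
    gsd = altitude_m / cam.focal_length_px
    cx, cy = cam.principal_point
    return (cx + (east_m - anchor_e) / gsd, cy - (north_m - anchor_n) / gsd)


def pixel_to_world(
    x_px: float,
    y_px: float,
    cam: CameraModel,
    altitude_m: float,
    anchor_e: float = 0.0,
    anchor_n: float = 0.0,
) -> tuple[float, float]:
    """Inverse of :func:`world_to_pixel` for a north-aligned nadir frame."""
    gsd = altitude_m / cam.focal_length_px
    cx, cy = cam.principal_point
    return (anchor_e + (x_px - cx) * gsd, anchor_n - (y_px - cy) * gsd)
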