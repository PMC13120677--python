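"""Annotation-table schema, readers/writers and unit conversion.

A single flat comma-separated table holds both sensor channels; ``sensor``
is a column because the RGB and thermal streams are time-synchronized
views of the same surfacing events.  Each row is one annotated landmark:
whale body landmarks (rostrum, tail, fluke notch, fluke tips) or
flukeprint landmarks (centroid, width endpoints, posterior/anterior
edges).  Rows may carry pixel coordinates, world east/north coordinates,
or both; world coordinates take precedence downstream to avoid double
application of photogrammetric scaling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError

__all__ = [
    "RECORD_TYPES",
    "PRINT_RECORD_TYPES",
    "MANDATORY_COLUMNS",
    "ANNOTATION_COLUMNS",
    "KNOT_M_S",
    "read_annotations",
    "write_annotations",
    "validate_annotations",
    "normalize_annotations",
    "convert_units",
]

RECORD_TYPES = frozenset(
    {
        "rostrum",
        "fluke_notch",
        "fluke_tip_left",
        "fluke_tip_right",
        "tail",
        "print_centroid",
        "print_width_left",
        "print_width_right",
        "print_posterior",
        "print_anterior",
    }
)
PRINT_RECORD_TYPES = frozenset(t for t in RECORD_TYPES if t.startswith("print_"))

MANDATORY_COLUMNS = ("record_type", "whale_id", "event_id", "timestamp_s", "sensor")
ANNOTATION_COLUMNS = (
    "record_type",
    "whale_id",
    "event_id",
    "print_id",
    "timestamp_s",
    "sensor",
    "x_px",
    "y_px",
    "x_m",
    "y_m",
    "altitude_m",
    "yaw_deg",
    "degraded",
    "emergence_offset_s",
    "age_class",
)

_DTYPES = {
    "record_type": "string",
    "whale_id": "string",
    "event_id": "Int64",
    "print_id": "Int64",
    "sensor": "string",
    "degraded": "Int64",
    "age_class": "string",
}

#: One international knot in metres per second (exact definition).
KNOT_M_S = 0.514444


def validate_annotations(df: pd.DataFrame) -> list[str]:
    """Collect row-level schema violations; returns an error report."""
    errors: list[str] = []
    unknown = set(df["record_type"].dropna()) - RECORD_TYPES
    if unknown:
        errors.append(f"unknown record types: {sorted(unknown)}")
    is_print = df["record_type"].isin(PRINT_RECORD_TYPES)
    missing_pid = df.index[is_print & df["print_id"].isna()]
    for i in missing_pid:
        errors.append(f"row {i}: print record lacks print_id")
    has_px = df["x_px"].notna() & df["y_px"].notna()
    has_m = df["x_m"].notna() & df["y_m"].notna()
    for i in df.index[~(has_px | has_m)]:
        errors.append(f"row {i}: neither pixel nor world coordinates present")
    neg_t = df.index[df["timestamp_s"] < 0]
    for i in neg_t:
        errors.append(f"row {i}: negative timestamp")
    return errors


def normalize_annotations(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ANNOTATION_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    for col, dtype in _DTYPES.items():
        out[col] = out[col].astype(dtype)
    for col in ("timestamp_s", "x_px", "y_px", "x_m", "y_m", "altitude_m",
                "yaw_deg", "emergence_offset_s"):
        out[col] = pd.to_numeric(out[col], errors="coerce").astype(float)
    # Keep unknown columns after the schema columns.
    extra = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    return out[list(ANNOTATION_COLUMNS) + extra]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate an annotation table from comma-separated text.

    Missing mandatory columns raise :class:`SchemaError` naming them; rows
    violating row-level constraints (print records without print_id,
    records without coordinates, negative timestamps) raise with the full
    error report.  An empty file with a valid header yields an empty
    table.  Unknown columns are preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    df = normalize_annotations(df)
    errors = validate_annotations(df)
    if errors:
        raise SchemaError(
            f"{len(errors)} malformed rows in {path}:\n" + "\n".join(errors[:50])
        )
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation table as comma-separated text (lossless floats)."""
    normalize_annotations(df).to_csv(path, index=False)


def convert_units(
    value: float, from_unit: str, to_unit: str, gsd: float | None = None
) -> float:
    """Convert between supported unit pairs.

    Supported: ``m/s`` <-> ``knot`` (1 knot = 0.514444 m/s) and ``m`` <->
    ``px`` given a ground sample distance ``gsd`` in m/px.  Composition
    with the inverse conversion is the identity.
    """
    aliases = {"m s-1": "m/s", "ms-1": "m/s", "knots": "knot", "kn": "knot"}
    f = aliases.get(from_unit, from_unit)
    t = aliases.get(to_unit, to_unit)
    if f == t:
        return float(value)
    if (f, t) == ("m/s", "knot"):
        return float(value) / KNOT_M_S
    if (f, t) == ("knot", "m/s"):
        return float(value) * KNOT_M_S
    if (f, t) in (("m", "px"), ("px", "m")):
        if gsd is None or not np.isfinite(gsd) or gsd <= 0:
            raise InvalidInputError("m <-> px conversion requires a positive GSD")
        return float(value) / gsd if (f, t) == ("m", "px") else float(value) * gsd
    raise InvalidInputError(f"unsupported unit pair {from_unit!r} -> {to_unit!r}")
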