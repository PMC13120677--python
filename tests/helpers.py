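"""Shared builders for hand-constructed annotation tables."""

from __future__ import annotations

import numpy as np
import pandas as pd


def ann_row(
    record_type: str,
    whale_id: str = "w0",
    event_id: int = 0,
    print_id=None,
    t: float = 0.0,
    sensor: str = "TIR",
    x: float = 0.0,
    y: float = 0.0,
    degraded: int = 0,
    offset: float = 1.0,
    age: str = "adult",
) -> dict:
    return dict(
        record_type=record_type,
        whale_id=whale_id,
        event_id=event_id,
        print_id=print_id,
        timestamp_s=t,
        sensor=sensor,
        x_px=np.nan,
        y_px=np.nan,
        x_m=x,
        y_m=y,
        altitude_m=90.0,
        yaw_deg=0.0,
        degraded=degraded,
        emergence_offset_s=offset,
        age_class=age,
    )


def ann_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["print_id"] = df["print_id"].astype("Int64")
    df["degraded"] = df["degraded"].astype("Int64")
    return df


def width_print(whale_id: str, event_id: int, print_id: int, width: float,
                offset: float = 1.0, degraded: int = 0, age: str = "adult") -> list[dict]:
    """Left/right width endpoints ``width`` metres apart along east."""
    half = width / 2.0
    common = dict(whale_id=whale_id, event_id=event_id, print_id=print_id,
                  offset=offset, degraded=degraded, age=age)
    return [
        ann_row("print_width_left", x=-half, y=0.0, **common),
        ann_row("print_width_right", x=half, y=0.0, **common),
    ]
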