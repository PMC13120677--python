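"""Circular statistics for heading agreement between thermal and RGB imagery.

A flukeprint's posterior edge diffuses earlier than its anterior edge, so the
posterior-to-anterior axis of the print points along the whale's direction of
travel.  The compass bearing of that vector (thermal channel) is compared
against the tail-to-rostrum body axis from synchronized RGB frames.  All
bearings are geographic: 0 deg = north, 90 deg = east, measured clockwise.

Agreement is quantified with standard directional statistics: circular mean
and mean resultant length, circular standard deviation sqrt(-2 ln Rbar),
the Rayleigh test of uniformity, and the Fisher–Lee circular correlation
for paired angles.  Paired differences are wrapped to (-180, 180] and
classified as Excellent (<=5 deg), Good (<=15 deg), Acceptable (<=20 deg)
or Discrepant (>20 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedBearingError,
)

__all__ = [
    "CircularSummary",
    "bearing_from_points",
    "wrap_difference",
    "circular_summary",
    "circular_correlation",
    "heading_pairs_from_annotations",
    "heading_agreement_report",
    "AGREEMENT_CATEGORIES",
]

#: Inclusive upper bounds (degrees) of the agreement categories; anything
#: above the last bound is Discrepant.
AGREEMENT_CATEGORIES = (("Excellent", 5.0), ("Good", 15.0), ("Acceptable", 20.0))


@dataclass(frozen=True)
class CircularSummary:
    """Summary statistics of a sample of compass bearings."""

    n: int
    circ_mean_deg: float
    resultant_length: float
    circ_sd_deg: float
    circ_sd_rad: float
    rayleigh_z: float
    rayleigh_p: float
    rayleigh_p_asymptotic: float
    mean_defined: bool


def bearing_from_points(
    from_point: Sequence[float], to_point: Sequence[float]
) -> float:
    """Compass bearing of the vector from one east/north point to another.

    Returns degrees in [0, 360) with 0 = north and 90 = east.
    """
    de = float(to_point[0]) - float(from_point[0])
    dn = float(to_point[1]) - float(from_point[1])
    if not (math.isfinite(de) and math.isfinite(dn)):
        raise InvalidInputError("non-finite coordinates")
    if de == 0.0 and dn == 0.0:
        raise UndefinedBearingError("bearing undefined for coincident points")
    return math.degrees(math.atan2(de, dn)) % 360.0


def wrap_difference(a: float, b: float) -> float:
    """Signed angular difference ``a - b`` wrapped into (-180, 180].

    The boundary case of exactly opposite bearings maps to +180 by
    convention.
    """
    if not (math.isfinite(a) and math.isfinite(b)):
        raise InvalidInputError("non-finite angle")
    d = (float(a) - float(b) + 180.0) % 360.0 - 180.0
    return 180.0 if d == -180.0 else d


def _resultant(angles_rad: np.ndarray) -> tuple[float, float]:
    """Mean direction (rad) and mean resultant length of a circular sample."""
    c = float(np.mean(np.cos(angles_rad)))
    s = float(np.mean(np.sin(angles_rad)))
    return math.atan2(s, c), math.hypot(c, s)


def circular_summary(angles_deg: Sequence[float]) -> CircularSummary:
    """Circular mean, resultant length, circular SD and Rayleigh test.

    The Rayleigh statistic is Z = n * Rbar**2; the reported p-value uses the
    small-sample refinement

        p = exp( sqrt(1 + 4n + 4(n^2 - Rv^2)) - (1 + 2n) ),   Rv = n * Rbar,

    with the asymptotic exp(-Z) also exposed for comparison.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 1:
        raise InsufficientDataError("at least one angle required")
    if not np.all(np.isfinite(angles)):
        raise InvalidInputError("non-finite angle")
    rad = np.radians(angles)
    mean_rad, rbar = _resultant(rad)
    n = angles.size
    mean_defined = rbar > 1e-12
    mean_deg = math.degrees(mean_rad) % 360.0 if mean_defined else float("nan")
    if mean_deg >= 360.0:  # guard the -0.0 % 360 -> 360.0 float artefact
        mean_deg = 0.0
    if rbar >= 1.0:
        sd_rad = 0.0
    elif rbar <= 0.0:
        sd_rad = float("inf")
    else:
        sd_rad = math.sqrt(-2.0 * math.log(rbar))
    z = n * rbar * rbar
    rv = n * rbar
    if n >= 2:
        p_asym = math.exp(-z)
        arg = 1.0 + 4.0 * n + 4.0 * (n * n - rv * rv)
        p_refined = min(1.0, math.exp(math.sqrt(arg) - (1.0 + 2.0 * n)))
    else:
        p_asym = float("nan")
        p_refined = float("nan")
    return CircularSummary(
        n=n,
        circ_mean_deg=mean_deg,
        resultant_length=rbar,
        circ_sd_deg=math.degrees(sd_rad),
        circ_sd_rad=sd_rad,
        rayleigh_z=z,
        rayleigh_p=p_refined,
        rayleigh_p_asymptotic=p_asym,
        mean_defined=mean_defined,
    )


def circular_correlation(
    a_deg: Sequence[float], b_deg: Sequence[float]
) -> tuple[float, float]:
    """Fisher–Lee circular correlation between two paired angle samples.

    r = sum sin(a - abar) sin(b - bbar) /
        sqrt( sum sin^2(a - abar) * sum sin^2(b - bbar) )

    with abar, bbar the circular means.  Returns ``(r, p)`` where the p-value
    comes from the standard asymptotic normal test.  Raises
    :class:`DegenerateFitError` analogue (InvalidInputError) when either
    series has zero circular variance.
    """
    a = np.radians(np.asarray(a_deg, dtype=float))
    b = np.radians(np.asarray(b_deg, dtype=float))
    if a.size != b.size:
        raise InvalidInputError("paired angle series must have equal length")
    if a.size < 3:
        raise InsufficientDataError("at least three pairs required")
    abar, _ = _resultant(a)
    bbar, _ = _resultant(b)
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    ssa, ssb = float(np.sum(sa**2)), float(np.sum(sb**2))
    if ssa < 1e-15 * a.size or ssb < 1e-15 * a.size:
        raise InvalidInputError("zero circular variance in one series")
    denom = math.sqrt(ssa * ssb)
    r = float(np.sum(sa * sb)) / denom
    # Fisher & Lee (1983) asymptotic test statistic.
    n = a.size
    l20 = float(np.mean(sa**2))
    l02 = float(np.mean(sb**2))
    l22 = float(np.mean(sa**2 * sb**2))
    if l22 > 0:
        z = math.sqrt(n * l20 * l02 / l22) * r
        p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    else:
        p = float("nan")
    return r, p


def _nearest_row(group: pd.DataFrame, t: float) -> pd.Series:
    idx = (group["timestamp_s"] - t).abs().idxmin()
    return group.loc[idx]


def heading_pairs_from_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Pair TIR print headings with RGB body-axis headings.

    The TIR heading of each print is the bearing of its posterior -> anterior
    vector; the RGB heading is the tail -> rostrum bearing at the RGB frame
    closest in time to the print's emergence.  Pairs are keyed by whale,
    surfacing event and sequential print identifier.
    """
    ann = annotations
    rows = []
    post = ann[ann["record_type"] == "print_posterior"]
    ante = ann[ann["record_type"] == "print_anterior"].set_index(
        ["whale_id", "event_id", "print_id"]
    )
    rgb = ann[ann["sensor"] == "RGB"]
    rostrum = {
        k: g.reset_index(drop=True)
        for k, g in rgb[rgb["record_type"] == "rostrum"].groupby(
            ["whale_id", "event_id"]
        )
    }
    tail = {
        k: g.reset_index(drop=True)
        for k, g in rgb[rgb["record_type"] == "tail"].groupby(
            ["whale_id", "event_id"]
        )
    }
    for _, p in post.iterrows():
        key = (p["whale_id"], p["event_id"], p["print_id"])
        if key not in ante.index:
            continue
        a = ante.loc[key]
        tir_heading = bearing_from_points(
            (p["x_m"], p["y_m"]), (a["x_m"], a["y_m"])
        )
        ev_key = (p["whale_id"], p["event_id"])
        if ev_key not in rostrum or ev_key not in tail:
            continue
        r = _nearest_row(rostrum[ev_key], p["timestamp_s"])
        t = _nearest_row(tail[ev_key], p["timestamp_s"])
        rgb_heading = bearing_from_points((t["x_m"], t["y_m"]), (r["x_m"], r["y_m"]))
        rows.append(
            {
                "whale_id": p["whale_id"],
                "event_id": p["event_id"],
                "print_id": p["print_id"],
                "tir_heading_deg": tir_heading,
                "rgb_heading_deg": rgb_heading,
                "difference_deg": wrap_difference(tir_heading, rgb_heading),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "whale_id",
            "event_id",
            "print_id",
            "tir_heading_deg",
            "rgb_heading_deg",
            "difference_deg",
        ],
    )


def classify_agreement(abs_difference_deg: float) -> str:
    for name, bound in AGREEMENT_CATEGORIES:
        if abs_difference_deg <= bound:
            return name
    return "Discrepant"


def _summary_dict(s: CircularSummary) -> dict:
    return {
        "n": s.n,
        "circ_mean_deg": s.circ_mean_deg,
        "resultant_length": s.resultant_length,
        "circ_sd_deg": s.circ_sd_deg,
        "circ_sd_rad": s.circ_sd_rad,
        "rayleigh_z": s.rayleigh_z,
        "rayleigh_p": s.rayleigh_p,
    }


def heading_agreement_report(pairs: pd.DataFrame) -> dict:
    """Full heading-agreement battery on a table of paired headings.

    Expects columns ``tir_heading_deg``, ``rgb_heading_deg`` and optionally
    ``whale_id`` (for per-individual summaries).  Differences are TIR - RGB,
    wrapped to (-180, 180].
    """
    if len(pairs) < 3:
        raise InsufficientDataError("at least three heading pairs required")
    tir = pairs["tir_heading_deg"].to_numpy(dtype=float)
    rgb = pairs["rgb_heading_deg"].to_numpy(dtype=float)
    diffs = np.array([wrap_difference(t, r) for t, r in zip(tir, rgb)])
    abs_diffs = np.abs(diffs)

    diff_summary = circular_summary(diffs)
    # Mean offset on (-180, 180]: the circular mean of differences re-wrapped.
    mean_offset = (
        wrap_difference(diff_summary.circ_mean_deg, 0.0)
        if diff_summary.mean_defined
        else float("nan")
    )
    corr, corr_p = circular_correlation(tir, rgb)

    categories = [classify_agreement(d) for d in abs_diffs]
    n = len(diffs)
    cat_counts = {name: 0 for name, _ in AGREEMENT_CATEGORIES}
    cat_counts["Discrepant"] = 0
    for c in categories:
        cat_counts[c] += 1
    cat_props = {k: 100.0 * v / n for k, v in cat_counts.items()}

    per_whale = {}
    if "whale_id" in pairs.columns:
        d = pairs.assign(_diff=diffs)
        for wid, g in d.groupby("whale_id"):
            s = circular_summary(g["_diff"].to_numpy())
            per_whale[str(wid)] = {
                "n": s.n,
                "mean_offset_deg": wrap_difference(s.circ_mean_deg, 0.0)
                if s.mean_defined
                else float("nan"),
                "circ_sd_deg": s.circ_sd_deg,
            }

    return {
        "n_pairs": n,
        "tir_summary": _summary_dict(circular_summary(tir)),
        "rgb_summary": _summary_dict(circular_summary(rgb)),
        "circ_correlation": corr,
        "circ_correlation_p": corr_p,
        "mean_offset_deg": mean_offset,
        "offset_circ_sd_deg": diff_summary.circ_sd_deg,
        "diff_rayleigh_z": diff_summary.rayleigh_z,
        "diff_rayleigh_p": diff_summary.rayleigh_p,
        "category_counts": cat_counts,
        "category_pct": cat_props,
        "mean_abs_error_deg": float(np.mean(abs_diffs)),
        "pct_below_20deg": 100.0 * float(np.mean(abs_diffs < 20.0)),
        "per_whale": per_whale,
    }
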