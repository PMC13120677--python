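"""Swimming-speed estimation and cross-sensor method agreement.

Two independent speed estimates are produced for each surfacing event:

* RGB channel — the manually tracked rostrum tip gives frame-to-frame
  Euclidean displacements; dividing by elapsed time and averaging yields a
  mean event speed.
* Thermal channel — successive flukeprint centroids along a linear
  trajectory are spaced by (speed x stroke period); inter-centroid distance
  divided by the corresponding time interval gives per-increment speeds
  that are averaged per event, with mean inter-centroid spacing retained
  for the spacing-to-speed model.

Paired event speeds (RGB as the reference) are compared with a standard
method-agreement battery: Bland–Altman bias and 95% limits of agreement,
RMSE / MAE / nRMSE, MAPE and median MAPE, ICC(A,1) under a two-way
random-effects absolute-agreement model, a paired t-test, proportional
bias, and Deming errors-in-variables calibration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "TrackedPositions",
    "FlukeprintSequence",
    "SpeedEstimate",
    "AgreementReport",
    "DemingFit",
    "rgb_track_speed",
    "tir_spacing_speed",
    "pair_events",
    "agreement_stats",
    "icc_a1",
    "deming_regression",
    "tracks_from_annotations",
    "print_sequences_from_annotations",
]

log = logging.getLogger(__name__)


@dataclass
class TrackedPositions:
    """Ordered rostrum-landmark positions for one whale and surfacing event."""

    whale_id: str
    event_id: int
    t_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.y_m = np.asarray(self.y_m, dtype=float)
        if not (len(self.t_s) == len(self.x_m) == len(self.y_m)):
            raise InvalidInputError("track arrays must have equal length")
        if len(self.t_s) >= 2 and not np.all(np.diff(self.t_s) > 0):
            raise InvalidInputError("track timestamps must be strictly increasing")


@dataclass
class FlukeprintSequence:
    """Ordered flukeprint records for one whale and surfacing event."""

    whale_id: str
    event_id: int
    print_id: np.ndarray
    t_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    degraded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.print_id = np.asarray(self.print_id, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.y_m = np.asarray(self.y_m, dtype=float)
        if self.degraded is None:
            self.degraded = np.zeros(len(self.t_s), dtype=bool)
        else:
            self.degraded = np.asarray(self.degraded, dtype=bool)
        order = np.argsort(self.print_id)
        for name in ("print_id", "t_s", "x_m", "y_m", "degraded"):
            setattr(self, name, getattr(self, name)[order])


@dataclass(frozen=True)
class SpeedEstimate:
    whale_id: str
    event_id: int
    method: str  # rgb_track | tir_spacing | still_prediction
    mean_speed_m_s: float
    n_increments: int
    mean_spacing_m: float | None = None


@dataclass(frozen=True)
class AgreementReport:
    n_pairs: int
    bias_m_s: float
    bias_ci: tuple[float, float]
    loa_low: float
    loa_high: float
    rmse_m_s: float
    mae_m_s: float
    nrmse: float
    mape_pct: float
    median_mape_pct: float
    mape_n: int
    icc_a1: float
    icc_ci: tuple[float, float]
    paired_t: float
    paired_t_df: int
    paired_t_p: float
    prop_bias_slope: float
    prop_bias_p: float
    pct_within_half: float
    pct_within_one: float


@dataclass(frozen=True)
class DemingFit:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    lam: float
    n: int
    slope_test_z: float = field(default=float("nan"))
    slope_test_p: float = field(default=float("nan"))
    intercept_test_z: float = field(default=float("nan"))
    intercept_test_p: float = field(default=float("nan"))


def rgb_track_speed(track: TrackedPositions, stride: int = 1) -> SpeedEstimate:
    """Mean of instantaneous rostrum speeds over consecutive frame pairs.

    ``stride`` subsamples the track (every ``stride``-th frame) before
    differencing; the default uses the native frame rate.
    """
    if stride < 1:
        raise InvalidInputError("stride must be >= 1")
    t = track.t_s[::stride]
    x = track.x_m[::stride]
    y = track.y_m[::stride]
    if len(t) < 2:
        raise InsufficientDataError("need at least two positions for a speed")
    dt = np.diff(t)
    d = np.hypot(np.diff(x), np.diff(y))
    speeds = d / dt
    return SpeedEstimate(
        whale_id=track.whale_id,
        event_id=track.event_id,
        method="rgb_track",
        mean_speed_m_s=float(np.mean(speeds)),
        n_increments=len(speeds),
    )


def tir_spacing_speed(seq: FlukeprintSequence) -> SpeedEstimate:
    """Event speed from successive flukeprint centroid spacing.

    Increments are formed only between consecutive print identifiers
    (gaps in the sequence are skipped); degraded prints are retained, as
    deformation affects size but not centroid-based movement analysis.
    """
    if len(seq.t_s) < 2:
        raise InsufficientDataError("need at least two prints for a speed")
    consecutive = np.diff(seq.print_id) == 1
    dt = np.diff(seq.t_s)
    if np.any(dt[consecutive] <= 0):
        raise InvalidInputError("print timestamps must be increasing")
    spacing = np.hypot(np.diff(seq.x_m), np.diff(seq.y_m))
    if not np.any(consecutive):
        raise InsufficientDataError("no consecutive print pairs in sequence")
    sp = spacing[consecutive]
    speeds = sp / dt[consecutive]
    return SpeedEstimate(
        whale_id=seq.whale_id,
        event_id=seq.event_id,
        method="tir_spacing",
        mean_speed_m_s=float(np.mean(speeds)),
        n_increments=int(np.sum(consecutive)),
        mean_spacing_m=float(np.mean(sp)),
    )


def pair_events(
    rgb: Sequence[SpeedEstimate], tir: Sequence[SpeedEstimate]
) -> pd.DataFrame:
    """Inner-join RGB and TIR event speeds on (whale_id, event_id)."""

    def _frame(ests: Sequence[SpeedEstimate], label: str) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "whale_id": [e.whale_id for e in ests],
                "event_id": [e.event_id for e in ests],
                f"{label}_speed_m_s": [e.mean_speed_m_s for e in ests],
            }
        )
        if label == "tir":
            df["mean_spacing_m"] = [e.mean_spacing_m for e in ests]
        if df.duplicated(["whale_id", "event_id"]).any():
            raise InvalidInputError(f"duplicate (whale_id, event_id) in {label} events")
        return df

    merged = _frame(rgb, "rgb").merge(
        _frame(tir, "tir"), on=["whale_id", "event_id"], how="inner"
    )
    n_unpaired = len(rgb) + len(tir) - 2 * len(merged)
    if len(merged) == 0:
        log.warning("no shared (whale_id, event_id) keys between sensors")
    elif n_unpaired:
        log.info("%d events were unpaired and dropped", n_unpaired)
    return merged


def icc_a1(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    McGraw–Wong formulation from the two-way ANOVA mean squares with n
    subjects and k = 2 raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The confidence interval follows the McGraw–Wong F-based construction.
    Perfectly identical ratings (all mean squares zero) are defined as
    ICC = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise InsufficientDataError("ICC requires >= 3 paired observations")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((data - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        # No variance anywhere: identical ratings agree perfectly.
        return 1.0, (1.0, 1.0)
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) CI for ICC(A,1).
    if mse > 0 and icc < 1.0:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (
            n * (msr - f1 * mse)
            / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        upper = (
            n * (f2 * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        )
    else:
        lower, upper = icc, icc
    return float(icc), (float(lower), float(upper))


def agreement_stats(pairs: pd.DataFrame) -> AgreementReport:
    """Method-agreement battery on paired event speeds.

    Differences are RGB - TIR (RGB is the observational reference).  MAPE
    is relative to the RGB speed; pairs with zero RGB speed are excluded
    from MAPE with a warning.
    """
    if len(pairs) < 3:
        raise InsufficientDataError("at least three paired events required")
    rgb = pairs["rgb_speed_m_s"].to_numpy(dtype=float)
    tir = pairs["tir_speed_m_s"].to_numpy(dtype=float)
    n = len(rgb)
    diffs = rgb - tir
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    tcrit = stats.t.ppf(0.975, n - 1)
    bias_ci = (bias - tcrit * sd / math.sqrt(n), bias + tcrit * sd / math.sqrt(n))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    rmse = float(np.sqrt(np.mean(diffs**2)))
    mae = float(np.mean(np.abs(diffs)))
    mean_obs = float(np.mean(rgb))
    nrmse = rmse / mean_obs if mean_obs != 0 else float("nan")

    nonzero = rgb != 0
    if not np.all(nonzero):
        log.warning("%d pairs with zero RGB speed excluded from MAPE", int(np.sum(~nonzero)))
    ape = np.abs(diffs[nonzero] / rgb[nonzero]) * 100.0
    mape = float(np.mean(ape)) if ape.size else float("nan")
    med_mape = float(np.median(ape)) if ape.size else float("nan")

    icc, icc_ci = icc_a1(rgb, tir)

    if sd > 0:
        t_stat = bias / (sd / math.sqrt(n))
        t_p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
    else:
        t_stat, t_p = float("nan"), float("nan")

    means = (rgb + tir) / 2.0
    if np.std(means) > 0:
        lr = stats.linregress(means, diffs)
        prop_slope, prop_p = float(lr.slope), float(lr.pvalue)
    else:
        prop_slope, prop_p = float("nan"), float("nan")

    return AgreementReport(
        n_pairs=n,
        bias_m_s=bias,
        bias_ci=bias_ci,
        loa_low=loa_low,
        loa_high=loa_high,
        rmse_m_s=rmse,
        mae_m_s=mae,
        nrmse=nrmse,
        mape_pct=mape,
        median_mape_pct=med_mape,
        mape_n=int(ape.size),
        icc_a1=icc,
        icc_ci=icc_ci,
        paired_t=t_stat,
        paired_t_df=n - 1,
        paired_t_p=t_p,
        prop_bias_slope=prop_slope,
        prop_bias_p=prop_p,
        pct_within_half=100.0 * float(np.mean(np.abs(diffs) <= 0.5)),
        pct_within_one=100.0 * float(np.mean(np.abs(diffs) <= 1.0)),
    )


def _deming_coefs(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, float]:
    xbar, ybar = float(np.mean(x)), float(np.mean(y))
    sxx = float(np.sum((x - xbar) ** 2)) / (len(x) - 1)
    syy = float(np.sum((y - ybar) ** 2)) / (len(x) - 1)
    sxy = float(np.sum((x - xbar) * (y - ybar))) / (len(x) - 1)
    if sxy == 0.0:
        raise DegenerateFitError("zero covariance: Deming slope undefined")
    slope = (syy - lam * sxx + math.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (
        2 * sxy
    )
    return slope, ybar - slope * xbar


def deming_regression(
    x: Sequence[float], y: Sequence[float], lam: float = 1.0
) -> DemingFit:
    """Errors-in-variables line fit with error-variance ratio ``lam``.

    Closed-form slope

        b = (Syy - lam Sxx + sqrt((Syy - lam Sxx)^2 + 4 lam Sxy^2)) / (2 Sxy)

    with intercept ybar - b xbar.  Standard errors come from the jackknife,
    and Wald tests of slope = 1 and intercept = 0 use the normal reference
    distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("Deming regression requires >= 3 pairs")
    if not (lam > 0):
        raise InvalidInputError("error-variance ratio must be positive")
    slope, intercept = _deming_coefs(x, y, lam)
    n = len(x)
    jk = np.empty((n, 2))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jk[i] = _deming_coefs(x[mask], y[mask], lam)
        mask[i] = True
    jk_mean = jk.mean(axis=0)
    var = (n - 1) / n * np.sum((jk - jk_mean) ** 2, axis=0)
    slope_se, intercept_se = float(np.sqrt(var[0])), float(np.sqrt(var[1]))

    def _wald(est: float, null: float, se: float) -> tuple[float, float]:
        if se == 0:
            return (float("inf") if est != null else 0.0), (0.0 if est != null else 1.0)
        z = (est - null) / se
        return z, 2.0 * stats.norm.sf(abs(z))

    sz, sp = _wald(slope, 1.0, slope_se)
    iz, ip = _wald(intercept, 0.0, intercept_se)
    return DemingFit(
        slope=slope,
        slope_se=slope_se,
        intercept=intercept,
        intercept_se=intercept_se,
        lam=lam,
        n=n,
        slope_test_z=sz,
        slope_test_p=sp,
        intercept_test_z=iz,
        intercept_test_p=ip,
    )


def tracks_from_annotations(
    annotations: pd.DataFrame, sensor: str = "RGB"
) -> list[TrackedPositions]:
    """Extract per-event rostrum tracks from an annotation table."""
    sub = annotations[
        (annotations["record_type"] == "rostrum") & (annotations["sensor"] == sensor)
    ]
    tracks = []
    for (wid, eid), g in sub.groupby(["whale_id", "event_id"]):
        g = g.sort_values("timestamp_s")
        tracks.append(
            TrackedPositions(
                whale_id=str(wid),
                event_id=int(eid),
                t_s=g["timestamp_s"].to_numpy(),
                x_m=g["x_m"].to_numpy(),
                y_m=g["y_m"].to_numpy(),
            )
        )
    return tracks


def print_sequences_from_annotations(
    annotations: pd.DataFrame,
) -> list[FlukeprintSequence]:
    """Extract per-event flukeprint centroid sequences (TIR channel)."""
    sub = annotations[
        (annotations["record_type"] == "print_centroid")
        & (annotations["sensor"] == "TIR")
    ]
    seqs = []
    for (wid, eid), g in sub.groupby(["whale_id", "event_id"]):
        seqs.append(
            FlukeprintSequence(
                whale_id=str(wid),
                event_id=int(eid),
                print_id=g["print_id"].to_numpy(dtype=int),
                t_s=g["timestamp_s"].to_numpy(dtype=float),
                x_m=g["x_m"].to_numpy(dtype=float),
                y_m=g["y_m"].to_numpy(dtype=float),
                degraded=g["degraded"].to_numpy(dtype=int).astype(bool)
                if "degraded" in g
                else None,
            )
        )
    return seqs
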