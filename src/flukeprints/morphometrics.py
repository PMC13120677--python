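"""Per-individual morphometry and size/age-class analyses.

Flukeprint width (the axis parallel to the fluke, perpendicular to the
swimming direction) carries a strong age-class signal: calf and adult
widths form separable clusters even though within-class scaling with body
size is weak.  This module summarises repeated measurements per
individual, fits the pooled / within-class / interaction regressions of
body size on flukeprint width with 10-fold cross-validation, and
evaluates age-class discrimination with a logistic model, ROC analysis
and the Youden-optimal width threshold.

Quality control: only prints annotated within 5 s of fluke emergence and
not flagged as degraded contribute to width means; degraded prints remain
available downstream for movement analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .errors import InsufficientDataError, InvalidDesignError, InvalidInputError
from .photogrammetry import CameraModel, FlightContext, measure_length

__all__ = [
    "QUALITY_WINDOW_S",
    "ScalingFit",
    "ClassifierFit",
    "summarize_individuals",
    "fit_scaling",
    "crossvalidate_scaling",
    "classify_age",
]

log = logging.getLogger(__name__)

#: Maximum delay (s) between fluke emergence and print annotation for a
#: width measurement to enter size analyses.
QUALITY_WINDOW_S = 5.0

_SCOPES = ("pooled", "adult", "calf", "interaction")
_RESPONSES = {"body_length": "mean_body_length_m", "fluke_span": "mean_fluke_span_m"}


@dataclass(frozen=True)
class ScalingFit:
    response: str
    scope: str
    n: int
    params: dict
    se: dict
    t_values: dict
    p_values: dict
    adj_r2: float
    r2: float
    rss: float
    interaction_f: float | None = None
    interaction_p: float | None = None


@dataclass(frozen=True)
class ClassifierFit:
    intercept: float
    coef_width: float
    separation_flag: bool
    deviance: float
    roc_points: list  # (threshold, sensitivity, specificity)
    auc: float
    youden_threshold_m: float
    youden_j: float
    sensitivity: float
    specificity: float
    confusion: dict  # tp/fp/tn/fn with adult as positive class
    accuracy: float
    n_calves: int = 0
    n_adults: int = 0


def _pair_distance(
    group: pd.DataFrame,
    left_type: str,
    right_type: str,
    keys: list[str],
    camera: CameraModel | None,
    flight: FlightContext | None,
) -> pd.DataFrame:
    """Distances between paired endpoint records sharing the same keys."""
    left = group[group["record_type"] == left_type]
    right = group[group["record_type"] == right_type]
    merged = left.merge(right, on=keys, suffixes=("_l", "_r"))
    dists = []
    for _, row in merged.iterrows():
        if np.isfinite(row.get("x_m_l", np.nan)) and np.isfinite(
            row.get("x_m_r", np.nan)
        ):
            d = float(np.hypot(row["x_m_l"] - row["x_m_r"], row["y_m_l"] - row["y_m_r"]))
        elif camera is not None and flight is not None:
            d = measure_length(
                (row["x_px_l"], row["y_px_l"]),
                (row["x_px_r"], row["y_px_r"]),
                camera,
                flight,
            )
        else:
            raise InvalidInputError(
                "records lack world coordinates and no camera/flight context given"
            )
        dists.append(d)
    merged = merged[keys].copy()
    merged["distance_m"] = dists
    return merged


def summarize_individuals(
    annotations: pd.DataFrame,
    tir_camera: CameraModel | None = None,
    rgb_camera: CameraModel | None = None,
    flight: FlightContext | None = None,
    quality_window_s: float = QUALITY_WINDOW_S,
) -> pd.DataFrame:
    """One morphometric record per whale from an annotation table.

    Width means use only quality-passing prints (annotated within
    ``quality_window_s`` of emergence and not degraded).  Body length is
    the rostrum to fluke-notch distance, fluke span the distance between
    fluke tips.  Whales without any valid width measurement are excluded
    with a logged warning.
    """
    ann = annotations
    keys_print = ["whale_id", "event_id", "print_id"]
    widths = _pair_distance(
        ann, "print_width_left", "print_width_right", keys_print, tir_camera, flight
    )
    # Attach quality flags from the left endpoint record.
    meta = ann[ann["record_type"] == "print_width_left"][
        keys_print + ["degraded", "emergence_offset_s"]
    ]
    widths = widths.merge(meta, on=keys_print, how="left")
    ok = (widths["emergence_offset_s"].fillna(0.0) <= quality_window_s) & (
        widths["degraded"].fillna(0).astype(int) == 0
    )
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("%d width measurements excluded by quality filters", n_excluded)
    widths = widths[ok]

    keys_frame = ["whale_id", "event_id", "timestamp_s"]
    lengths = _pair_distance(
        ann, "rostrum", "fluke_notch", keys_frame, rgb_camera, flight
    )
    spans = _pair_distance(
        ann, "fluke_tip_left", "fluke_tip_right", keys_frame, rgb_camera, flight
    )

    age = (
        ann.dropna(subset=["age_class"])
        .groupby("whale_id")["age_class"]
        .first()
        if "age_class" in ann.columns
        else pd.Series(dtype=object)
    )

    rows = []
    for wid in sorted(ann["whale_id"].unique()):
        w = widths[widths["whale_id"] == wid]["distance_m"]
        if len(w) == 0:
            log.warning("whale %s has no valid width measurements; excluded", wid)
            continue
        ln = lengths[lengths["whale_id"] == wid]["distance_m"]
        sp = spans[spans["whale_id"] == wid]["distance_m"]
        rows.append(
            {
                "whale_id": wid,
                "age_class": age.get(wid, None),
                "mean_flukeprint_width_m": float(w.mean()),
                "mean_body_length_m": float(ln.mean()) if len(ln) else np.nan,
                "mean_fluke_span_m": float(sp.mean()) if len(sp) else np.nan,
                "n_measurements": int(len(w)),
            }
        )
    return pd.DataFrame(rows)


def _design(summaries: pd.DataFrame, response: str, scope: str):
    if response not in _RESPONSES:
        raise InvalidInputError(f"unknown response {response!r}")
    if scope not in _SCOPES:
        raise InvalidInputError(f"unknown scope {scope!r}")
    ycol = _RESPONSES[response]
    data = summaries.dropna(subset=[ycol, "mean_flukeprint_width_m"]).copy()
    if scope in ("adult", "calf"):
        data = data[data["age_class"] == scope]
    if scope == "interaction":
        classes = set(data["age_class"].dropna())
        if len(classes) < 2:
            raise InvalidDesignError("interaction model requires both age classes")
    if len(data) < 3:
        raise InsufficientDataError(f"fewer than 3 whales in scope {scope!r}")
    y = data[ycol].to_numpy(dtype=float)
    w = data["mean_flukeprint_width_m"].to_numpy(dtype=float)
    if scope == "interaction":
        is_adult = (data["age_class"] == "adult").to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(w), w, is_adult, w * is_adult])
        names = ["intercept", "width", "class_adult", "width:class_adult"]
    else:
        X = np.column_stack([np.ones_like(w), w])
        names = ["intercept", "width"]
    return y, X, names, data


def fit_scaling(summaries: pd.DataFrame, response: str, scope: str) -> ScalingFit:
    """OLS of mean body length (or fluke span) on mean flukeprint width.

    ``scope`` selects the pooled regression, the within-class regressions,
    or the interaction model ``response ~ width + class + width:class``
    whose interaction term is tested with a partial F-test against the
    additive model.
    """
    y, X, names, _ = _design(summaries, response, scope)
    res = sm.OLS(y, X).fit()
    # A response with no variance explains nothing rather than "negative".
    degenerate = float(res.centered_tss) <= 1e-12 * max(1.0, float(np.sum(y**2)))
    r2 = 0.0 if degenerate else float(res.rsquared)
    adj_r2 = 0.0 if degenerate else float(res.rsquared_adj)
    inter_f = inter_p = None
    if scope == "interaction":
        res_add = sm.OLS(y, X[:, :3]).fit()
        df_resid = res.df_resid
        f = (res_add.ssr - res.ssr) / 1.0 / (res.ssr / df_resid)
        inter_f = float(f)
        inter_p = float(sps.f.sf(f, 1, df_resid))
    return ScalingFit(
        response=response,
        scope=scope,
        n=len(y),
        params={k: float(v) for k, v in zip(names, res.params)},
        se={k: float(v) for k, v in zip(names, res.bse)},
        t_values={k: float(v) for k, v in zip(names, res.tvalues)},
        p_values={k: float(v) for k, v in zip(names, res.pvalues)},
        adj_r2=adj_r2,
        r2=r2,
        rss=float(res.ssr),
        interaction_f=inter_f,
        interaction_p=inter_p,
    )


def crossvalidate_scaling(
    summaries: pd.DataFrame,
    response: str,
    scope: str,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """K-fold cross-validated RMSE and held-out R^2 of a scaling model.

    Folds are simple random splits with a fixed seed.  Held-out R^2 is
    1 - SSE/SST over the pooled held-out predictions, so a response with
    no signal scores at or below zero.  ``k`` is reduced with a warning
    when the scope holds fewer observations than folds.
    """
    y, X, _, _ = _design(summaries, response, scope)
    n = len(y)
    if n < k:
        log.warning("reducing folds from %d to %d (only %d observations)", k, n, n)
        k = n
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(n)
    for train, test in kf.split(X):
        beta = np.linalg.lstsq(X[train], y[train], rcond=None)[0]
        pred[test] = X[test] @ beta
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    rmse = float(np.sqrt(sse / n))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return rmse, r2


def _roc_scan(calf_w: np.ndarray, adult_w: np.ndarray):
    """ROC over width thresholds, predicting adult when width > threshold."""
    widths = np.sort(np.unique(np.concatenate([calf_w, adult_w])))
    # Candidate thresholds: below the minimum, each gap midpoint, above max.
    mids = (widths[:-1] + widths[1:]) / 2.0 if len(widths) > 1 else np.array([])
    cands = np.concatenate([[widths[0] - 1.0], mids, [widths[-1] + 1.0]])
    points = []
    for t in cands:
        sens = float(np.mean(adult_w > t))
        spec = float(np.mean(calf_w <= t))
        points.append((float(t), sens, spec))
    return points


def classify_age(summaries: pd.DataFrame) -> ClassifierFit:
    """Age-class discrimination from mean flukeprint width alone.

    Fits a logistic model of class on width (iteration-capped; complete
    separation is flagged rather than raised), computes the ROC directly
    over width thresholds — monotone-equivalent to probability thresholds
    for a single monotone predictor — and selects the Youden-optimal
    threshold.  Ties in J are broken towards the smallest threshold, and
    the reported threshold is the midpoint of the gap between the adjacent
    observed widths.  AUC equals the Mann–Whitney probability that a
    random adult's width exceeds a random calf's.
    """
    data = summaries.dropna(subset=["age_class", "mean_flukeprint_width_m"])
    classes = set(data["age_class"])
    if not {"calf", "adult"} <= classes or any(
        (data["age_class"] == c).sum() < 2 for c in ("calf", "adult")
    ):
        raise InvalidDesignError("both classes with >= 2 whales each are required")
    calf_w = data.loc[data["age_class"] == "calf", "mean_flukeprint_width_m"].to_numpy()
    adult_w = data.loc[
        data["age_class"] == "adult", "mean_flukeprint_width_m"
    ].to_numpy()

    X = data["mean_flukeprint_width_m"].to_numpy().reshape(-1, 1)
    y = (data["age_class"] == "adult").to_numpy(dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(C=np.inf, max_iter=200).fit(X, y)
    p = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    deviance = -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    separated = float(np.max(calf_w)) < float(np.min(adult_w))

    points = _roc_scan(calf_w, adult_w)
    js = [s + sp - 1.0 for _, s, sp in points]
    best = int(np.argmax(js))  # argmax returns the first (smallest threshold) tie
    jmax = js[best]
    # Place the threshold at the midpoint of the data gap it sits in.
    widths = np.sort(np.unique(np.concatenate([calf_w, adult_w])))
    t_raw = points[best][0]
    below = widths[widths <= t_raw]
    above = widths[widths > t_raw]
    if len(below) and len(above):
        threshold = float((below[-1] + above[0]) / 2.0)
    else:
        threshold = float(t_raw)
    sens = float(np.mean(adult_w > threshold))
    spec = float(np.mean(calf_w <= threshold))

    # AUC as the Mann-Whitney probability (ties count half).
    gt = np.sum(adult_w[:, None] > calf_w[None, :])
    eq = np.sum(adult_w[:, None] == calf_w[None, :])
    auc = float((gt + 0.5 * eq) / (len(adult_w) * len(calf_w)))

    tp = int(np.sum(adult_w > threshold))
    fn = len(adult_w) - tp
    tn = int(np.sum(calf_w <= threshold))
    fp = len(calf_w) - tn
    return ClassifierFit(
        intercept=float(clf.intercept_[0]),
        coef_width=float(clf.coef_[0, 0]),
        separation_flag=bool(separated),
        deviance=deviance,
        roc_points=points,
        auc=auc,
        youden_threshold_m=threshold,
        youden_j=float(jmax),
        sensitivity=sens,
        specificity=spec,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        accuracy=float((tp + tn) / (tp + tn + fp + fn)),
        n_calves=len(calf_w),
        n_adults=len(adult_w),
    )
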