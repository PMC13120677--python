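"""Log-log random-intercept model linking flukeprint spacing to speed.

The spacing between successive flukeprints integrates stroke amplitude and
period into a surface-visible proxy of horizontal speed.  Per surfacing
event j of whale i the model is

    log(speed_ij) = beta0 + beta1 * log(spacing_ij) + u_i + eps_ij,

with u_i ~ N(0, sigma_u^2) a whale-level random intercept absorbing
repeated measurements and eps_ij ~ N(0, sigma_e^2) residual error.  Natural
logarithms are used throughout, so the log-normal back-transform has
median exp(eta) and mean exp(eta + (sigma_u^2 + sigma_e^2)/2) for a new
whale.

Explanatory power is summarised by the Nakagawa–Schielzeth marginal and
conditional R^2; predictive skill by leave-one-whale-out cross-validation
with population-level (u = 0) predictions; and calibration by Deming
regression of predictions on observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError
from .kinematics import DemingFit, deming_regression

__all__ = [
    "LMMFit",
    "PredictionResult",
    "CVReport",
    "fit_loglog_lmm",
    "loocv_by_whale",
    "predict_still",
    "calibrate_predictions",
]

log = logging.getLogger(__name__)

#: Relative threshold below which the random-intercept variance is treated
#: as sitting on the zero boundary and the fit collapses to OLS.
_BOUNDARY_TOL = 1e-8


@dataclass(frozen=True)
class LMMFit:
    beta0: float
    beta0_se: float
    beta1: float
    beta1_se: float
    sigma_u2: float
    sigma_e2: float
    cov_fixed: np.ndarray  # 2x2 covariance of (beta0, beta1)
    r2_marginal: float
    r2_conditional: float
    n_events: int
    n_whales: int
    estimation: str  # "REML" | "ML" | "OLS"
    converged: bool = True
    boundary: bool = False
    single_group: bool = False
    body_length_beta: float | None = None


@dataclass(frozen=True)
class PredictionResult:
    spacing_m: float
    median_speed_m_s: float
    mean_speed_bias_corrected_m_s: float
    pi_low_m_s: float
    pi_high_m_s: float


@dataclass(frozen=True)
class CVReport:
    rmse_m_s: float
    mape_pct: float
    pi_coverage_pct: float
    predictions: pd.DataFrame
    folds: list = field(default_factory=list)
    n_failed_folds: int = 0


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    for col in ("whale_id", "spacing_m", "speed_m_s"):
        if col not in events.columns:
            raise InvalidInputError(f"events table missing column {col!r}")
    if len(events) == 0:
        raise InsufficientDataError("empty events table")
    if not np.all(events["spacing_m"] > 0) or not np.all(events["speed_m_s"] > 0):
        raise InvalidInputError("spacings and speeds must be strictly positive")
    return events


def _ols_fit(y: np.ndarray, X: np.ndarray, n_whales: int, estimation: str) -> LMMFit:
    res = sm.OLS(y, X).fit()
    beta = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    sigma_e2 = float(res.mse_resid)
    sigma_f2 = float(np.var(X @ beta, ddof=1))
    total = sigma_f2 + sigma_e2
    return LMMFit(
        beta0=float(beta[0]),
        beta0_se=float(np.sqrt(cov[0, 0])),
        beta1=float(beta[1]),
        beta1_se=float(np.sqrt(cov[1, 1])),
        sigma_u2=0.0,
        sigma_e2=sigma_e2,
        cov_fixed=cov[:2, :2],
        r2_marginal=sigma_f2 / total if total > 0 else float("nan"),
        r2_conditional=sigma_f2 / total if total > 0 else float("nan"),
        n_events=len(y),
        n_whales=n_whales,
        estimation=estimation,
        converged=True,
        boundary=True,
        single_group=n_whales == 1,
    )


def fit_loglog_lmm(
    events: pd.DataFrame,
    estimation: str = "REML",
    include_body_length: bool = False,
) -> LMMFit:
    """Fit the random-intercept model of log speed on log spacing.

    Parameters
    ----------
    events:
        One row per surfacing event with columns ``whale_id``,
        ``spacing_m`` (mean inter-centroid spacing) and ``speed_m_s``
        (mean event speed); ``body_length_m`` if ``include_body_length``.
    estimation:
        ``"REML"`` (default) or ``"ML"``; ML is appropriate when comparing
        fixed-effect structures.
    include_body_length:
        Add log body length as a second fixed effect (off by default; it is
        retained only when it improves fit).

    Notes
    -----
    With a single whale the random intercept is unidentifiable and the fit
    degenerates to OLS with a warning.  When the REML/ML estimate of
    sigma_u^2 sits on the zero boundary (below ``1e-8`` of the total
    variance) the fixed effects are replaced by their exact OLS values,
    which the mixed model approaches in that limit.
    """
    if estimation not in ("REML", "ML"):
        raise InvalidInputError("estimation must be 'REML' or 'ML'")
    events = _validate_events(events)
    y = np.log(events["speed_m_s"].to_numpy(dtype=float))
    logs = np.log(events["spacing_m"].to_numpy(dtype=float))
    cols = [np.ones_like(logs), logs]
    if include_body_length:
        if "body_length_m" not in events.columns:
            raise InvalidInputError("body_length_m column required")
        cols.append(np.log(events["body_length_m"].to_numpy(dtype=float)))
    X = np.column_stack(cols)
    groups = events["whale_id"].to_numpy()
    n_whales = len(pd.unique(groups))

    if n_whales == 1:
        log.warning("single whale: sigma_u^2 unidentifiable, falling back to OLS")
        return _ols_fit(y, X, n_whales, estimation)

    model = sm.MixedLM(y, X, groups=groups)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=(estimation == "REML"), method=method, maxiter=500)
            except Exception:  # noqa: BLE001 - optimizer failures are retried
                continue
            res = cand
            if getattr(cand, "converged", True):
                break
    if res is None:
        raise InvalidInputError("mixed-model optimisation failed for all methods")

    sigma_u2 = float(np.asarray(res.cov_re)[0, 0])
    sigma_e2 = float(res.scale)
    if sigma_u2 <= _BOUNDARY_TOL * (sigma_u2 + sigma_e2):
        fit = _ols_fit(y, X, n_whales, estimation)
        return fit

    k_fe = X.shape[1]
    beta = np.asarray(res.params, dtype=float)[:k_fe]
    cov = np.asarray(res.cov_params(), dtype=float)[:k_fe, :k_fe]
    sigma_f2 = float(np.var(X @ beta, ddof=1))
    total = sigma_f2 + sigma_u2 + sigma_e2
    return LMMFit(
        beta0=float(beta[0]),
        beta0_se=float(np.sqrt(cov[0, 0])),
        beta1=float(beta[1]),
        beta1_se=float(np.sqrt(cov[1, 1])),
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        cov_fixed=cov[:2, :2],
        r2_marginal=sigma_f2 / total,
        r2_conditional=(sigma_f2 + sigma_u2) / total,
        n_events=len(y),
        n_whales=n_whales,
        estimation=estimation,
        converged=bool(getattr(res, "converged", True)),
        body_length_beta=float(beta[2]) if include_body_length else None,
    )


def predict_still(
    fit: LMMFit, spacing_m: float, pi_level: float = 0.95
) -> PredictionResult:
    """Predict new-whale speed from a single still-image spacing.

    On the log scale eta = beta0 + beta1 log(spacing) with predictive
    variance v = x' V x + sigma_u^2 + sigma_e^2, propagating fixed-effect
    uncertainty, random-intercept variance and residual variance.  The
    back-transform reports the log-normal median exp(eta), the
    bias-corrected mean exp(eta + (sigma_u^2 + sigma_e^2)/2) and the
    95% prediction interval exp(eta +/- z sqrt(v)).
    """
    if not (spacing_m > 0):
        raise InvalidInputError("spacing must be strictly positive")
    x = np.array([1.0, np.log(spacing_m)])
    eta = float(x @ np.array([fit.beta0, fit.beta1]))
    v = float(x @ fit.cov_fixed @ x) + fit.sigma_u2 + fit.sigma_e2
    z = stats.norm.ppf(0.5 + pi_level / 2.0)
    half = z * np.sqrt(max(v, 0.0))
    return PredictionResult(
        spacing_m=float(spacing_m),
        median_speed_m_s=float(np.exp(eta)),
        mean_speed_bias_corrected_m_s=float(
            np.exp(eta + (fit.sigma_u2 + fit.sigma_e2) / 2.0)
        ),
        pi_low_m_s=float(np.exp(eta - half)),
        pi_high_m_s=float(np.exp(eta + half)),
    )


def loocv_by_whale(
    events: pd.DataFrame,
    estimation: str = "REML",
    pi_level: float = 0.95,
) -> CVReport:
    """Leave-one-whale-out cross-validation of the spacing-to-speed model.

    For each whale, all of its surfacing events are withheld, the model is
    refitted on the remainder, and the withheld events are predicted at the
    population level (u = 0) and back-transformed with the log-normal
    median.  RMSE and MAPE are reported on the original (m/s) scale, and
    ``pi_coverage_pct`` is the share of observed speeds inside the
    back-transformed prediction intervals.
    """
    events = _validate_events(events)
    whales = pd.unique(events["whale_id"])
    if len(whales) < 3:
        raise InsufficientDataError("leave-one-whale-out requires >= 3 whales")
    rows = []
    folds = []
    n_failed = 0
    for wid in whales:
        train = events[events["whale_id"] != wid]
        test = events[events["whale_id"] == wid]
        try:
            fit = fit_loglog_lmm(train, estimation=estimation)
        except Exception as exc:  # noqa: BLE001 - fold-level failure is reported
            log.warning("fold for whale %s failed: %s", wid, exc)
            n_failed += 1
            continue
        folds.append(
            {
                "held_out": str(wid),
                "n_train_events": len(train),
                "train_whales": sorted(str(w) for w in pd.unique(train["whale_id"])),
            }
        )
        for _, ev in test.iterrows():
            pred = predict_still(fit, float(ev["spacing_m"]), pi_level=pi_level)
            rows.append(
                {
                    "whale_id": str(wid),
                    "spacing_m": float(ev["spacing_m"]),
                    "observed_m_s": float(ev["speed_m_s"]),
                    "predicted_m_s": pred.median_speed_m_s,
                    "pi_low_m_s": pred.pi_low_m_s,
                    "pi_high_m_s": pred.pi_high_m_s,
                }
            )
    preds = pd.DataFrame(rows)
    err = preds["predicted_m_s"] - preds["observed_m_s"]
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = float(np.mean(np.abs(err / preds["observed_m_s"])) * 100.0)
    covered = (preds["observed_m_s"] >= preds["pi_low_m_s"]) & (
        preds["observed_m_s"] <= preds["pi_high_m_s"]
    )
    return CVReport(
        rmse_m_s=rmse,
        mape_pct=mape,
        pi_coverage_pct=100.0 * float(np.mean(covered)),
        predictions=preds,
        folds=folds,
        n_failed_folds=n_failed,
    )


def calibrate_predictions(
    predicted: np.ndarray, observed: np.ndarray, lam: float = 1.0
) -> DemingFit:
    """Deming calibration of predicted against observed speeds.

    Fits predicted = a + b * observed with errors in both variables and
    tests slope = 1 and intercept = 0; a well-calibrated predictor passes
    both.
    """
    return deming_regression(observed, predicted, lam=lam)
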