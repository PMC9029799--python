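"""Per-participant metabolic calibration of HRV.

Each participant gets an ordinary-least-squares regression of minute-level
RMSSD (ms) on activity energy expenditure, fitted over the whole recording
(or an explicit calibration sub-range for prospective use).  The fitted line
is the metabolically *expected* RMSSD: trigger detection later asks whether
the observed RMSSD falls meaningfully below it.

Two predictor conventions are supported:

``linear``
    RMSSD ~ AEE.  The intercept is the participant's HRV at rest (no
    movement); slopes are expected negative.
``inverse``
    RMSSD ~ 1/(AEE + eps).  Here the intercept is the HRV at very high
    movement; ``eps`` regularises the reciprocal at zero movement.

Units: AEE enters the fit as kcal per minute, so slopes are stored in
ms per (kcal/min).  Cohort summaries report slopes per 1000 kcal/24 h
(divide by 1.44), the convention used in ambulatory HRV reports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries_io import ParticipantSeries

#: 1 kcal/min expressed in units of (1000 kcal per 24 h)
KCAL_PER_MIN_TO_1000KCAL_PER_DAY = 1440.0 / 1000.0

MIN_CALIBRATION_MINUTES = 10


class DataSufficiencyError(ValueError):
    """Too few valid minutes to calibrate."""


class DegenerateFitError(ValueError):
    """Predictor has zero variance; the regression is undefined."""


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted per-participant calibration regression and its context."""

    participant_id: str
    predictor_kind: str  # "linear" | "inverse"
    intercept: float  # ms
    slope: float  # ms per predictor unit (kcal/min, or its reciprocal)
    pearson_r: float  # corr(rmssd, aee), negative expected
    sd_rmssd_cal: float  # ms, SD of valid calibration RMSSD
    mean_aee_cal: float  # kcal/min over valid calibration minutes
    epsilon: float  # kcal, inverse-variant regulariser (0 for linear)
    n_used: int
    n_removed: int = 0
    mean_rmssd_cal: float = float("nan")  # ms, for cohort summaries
    total_aee_cal: float = float("nan")  # kcal summed over valid minutes

    def predictor(self, aee) -> np.ndarray:
        """Map raw AEE (kcal/min) onto the regression predictor scale."""
        aee = np.asarray(aee, dtype=float)
        if self.predictor_kind == "inverse":
            return 1.0 / (aee + self.epsilon)
        return aee


def _calibration_mask(series: ParticipantSeries, cal_range) -> np.ndarray:
    mask = series.usable()
    if cal_range is not None:
        lo, hi = cal_range
        inside = (series.minute >= lo) & (series.minute < hi)
        mask = mask & inside
    return mask


def default_epsilon(aee: np.ndarray) -> float:
    """Inverse-variant regulariser: 5th percentile of the positive AEE values."""
    positive = aee[np.isfinite(aee) & (aee > 0)]
    if positive.size == 0:
        return 1e-3
    return float(np.percentile(positive, 5))


def fit_calibration(
    series: ParticipantSeries,
    predictor_kind: str = "linear",
    epsilon: Optional[float] = None,
    cal_range: Optional[tuple[int, int]] = None,
    n_removed: int = 0,
) -> CalibrationModel:
    """OLS of RMSSD on the chosen predictor over valid calibration minutes.

    ``cal_range`` restricts calibration to minutes in ``[lo, hi)``; by
    default the entire recording calibrates the model.  ``pearson_r`` is
    always the plain correlation between RMSSD and AEE (negative expected),
    regardless of predictor kind, so cohorts are comparable across variants.
    """
    if predictor_kind not in ("linear", "inverse"):
        raise ValueError(f"unknown predictor_kind {predictor_kind!r}")
    mask = _calibration_mask(series, cal_range)
    n = int(mask.sum())
    if n < MIN_CALIBRATION_MINUTES:
        raise DataSufficiencyError(
            f"{series.participant_id}: only {n} valid calibration minutes "
            f"(need >= {MIN_CALIBRATION_MINUTES})"
        )
    rmssd = series.rmssd[mask]
    aee = series.aee[mask]

    if predictor_kind == "inverse":
        eps = default_epsilon(aee) if epsilon is None else float(epsilon)
        if eps <= 0:
            raise ValueError("inverse variant requires epsilon > 0")
        x = 1.0 / (aee + eps)
    else:
        eps = 0.0
        x = aee

    if np.ptp(x) == 0:
        raise DegenerateFitError(
            f"{series.participant_id}: predictor has zero variance"
        )
    fit = stats.linregress(x, rmssd)
    if np.ptp(aee) == 0 or np.ptp(rmssd) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(rmssd, aee).statistic)
    return CalibrationModel(
        participant_id=series.participant_id,
        predictor_kind=predictor_kind,
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        pearson_r=r,
        sd_rmssd_cal=float(np.std(rmssd, ddof=1)),
        mean_aee_cal=float(np.mean(aee)),
        epsilon=eps,
        n_used=n,
        n_removed=n_removed,
        mean_rmssd_cal=float(np.mean(rmssd)),
        total_aee_cal=float(np.sum(aee)),
    )


def screen_outliers(
    series: ParticipantSeries,
    max_abs_studentized_residual: float = 4.0,
    cap: int = 5,
    cal_range: Optional[tuple[int, int]] = None,
) -> tuple[ParticipantSeries, int]:
    """Iteratively invalidate gross outliers from the RMSSD~AEE fit.

    At each pass the single worst minute whose externally studentized
    residual exceeds the threshold in absolute value is marked invalid and
    the regression is refitted; screening stops when no minute exceeds the
    threshold or ``cap`` minutes have been removed.  The default threshold
    of 4.0 keeps removals rare on artifact-free days (a handful per cohort),
    mirroring how sparse manual screening is in practice.

    Returns a cleaned copy of the series and the number of minutes removed.
    The operation is idempotent: re-screening the cleaned series removes
    nothing further.
    """
    import statsmodels.api as sm

    cleaned = series.copy()
    n_removed = 0
    while n_removed < cap:
        mask = _calibration_mask(cleaned, cal_range)
        idx = np.flatnonzero(mask)
        if idx.size < MIN_CALIBRATION_MINUTES:
            raise DataSufficiencyError(
                f"{series.participant_id}: only {idx.size} valid minutes "
                f"(need >= {MIN_CALIBRATION_MINUTES})"
            )
        x = sm.add_constant(cleaned.aee[idx])
        res = sm.OLS(cleaned.rmssd[idx], x).fit()
        student = res.get_influence().resid_studentized_external
        worst = int(np.nanargmax(np.abs(student)))
        if not np.isfinite(student[worst]) or abs(student[worst]) <= max_abs_studentized_residual:
            break
        cleaned.valid[idx[worst]] = False
        n_removed += 1
    return cleaned, n_removed


def summarize_calibrations(models: Sequence[CalibrationModel]) -> pd.DataFrame:
    """Cohort descriptive statistics of the individual calibration parameters.

    Returns a frame with rows (rmssd_ms, aee_kcal, intercept,
    slope_per_1000kcal, r) and columns (M, SD, Max, Min), the layout used
    for cohort calibration reports.  ``aee_kcal`` is the per-day total;
    slopes are converted from ms per (kcal/min) to ms per 1000 kcal/24 h.
    """
    if not models:
        raise ValueError("no calibration models to summarize")
    rows = {
        "rmssd_ms": [m.mean_rmssd_cal for m in models],
        "aee_kcal": [m.total_aee_cal for m in models],
        "intercept": [m.intercept for m in models],
        "slope_per_1000kcal": [
            m.slope / KCAL_PER_MIN_TO_1000KCAL_PER_DAY for m in models
        ],
        "r": [m.pearson_r for m in models],
    }
    out = {}
    for name, values in rows.items():
        v = np.asarray(values, dtype=float)
        out[name] = {
            "M": float(np.mean(v)),
            "SD": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "Max": float(np.max(v)),
            "Min": float(np.min(v)),
        }
    return pd.DataFrame(out).T[["M", "SD", "Max", "Min"]]


def calibrations_to_frame(models: Sequence[CalibrationModel]) -> pd.DataFrame:
    """Flat per-participant audit table (one row per calibration model)."""
    return pd.DataFrame(
        {
            "participant": [m.participant_id for m in models],
            "predictor_kind": [m.predictor_kind for m in models],
            "intercept": [m.intercept for m in models],
            "slope_per_kcal_min": [m.slope for m in models],
            "slope_per_1000kcal": [
                m.slope / KCAL_PER_MIN_TO_1000KCAL_PER_DAY for m in models
            ],
            "r": [m.pearson_r for m in models],
            "sd_rmssd_cal": [m.sd_rmssd_cal for m in models],
            "mean_aee_cal": [m.mean_aee_cal for m in models],
            "mean_rmssd_cal": [m.mean_rmssd_cal for m in models],
            "total_aee_cal": [m.total_aee_cal for m in models],
            "epsilon": [m.epsilon for m in models],
            "n_used": [m.n_used for m in models],
            "n_removed": [m.n_removed for m in models],
        }
    )
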