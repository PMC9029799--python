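"""Static, dynamic and inverse AddHRVr trigger algorithms.

An *additional HRV reduction* (AddHRVr) is a drop of observed RMSSD below
the metabolically expected RMSSD by more than a calibrated margin.  The
engine replays the online algorithm over a recorded (or generated) day,
strictly causally:

1. every valid minute is classified as a *meaningful decrease* when

       rmssd(t) < expected_rmssd(t) - decrease_mult * sd_rmssd_cal

2. a trigger fires at minute ``t`` when at least ``window_threshold`` of
   the trailing ``window_length`` minutes (``t-n+1 .. t`` inclusive) are
   meaningful decreases — the k-out-of-n rule — and strictly more than
   ``silent_min`` minutes have elapsed since the previous trigger.

The *static* variant predicts expected RMSSD from the fixed calibration
line.  The *dynamic* variant replaces the intercept minute-by-minute with
the mean of a 60-min HRV buffer so the threshold tracks slow HRV drifts:
the buffer absorbs observed RMSSD only while the trailing 40-min mean AEE
is below the calibration mean (otherwise the static intercept is pushed,
because movement-loaded HRV would contaminate the resting level).  The
*inverse* variant runs the static logic on a calibration of RMSSD against
the reciprocal of movement.

Invalid minutes never count as decreases but stay inside windows, so the
real-time behaviour under signal dropouts is deterministic.  Buffers are
lag-1: the intercept used at minute ``t`` is computed before minute ``t``
is pushed, so a minute cannot dilute its own threshold.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .timeseries_io import ParticipantSeries

VARIANTS = ("static", "dynamic", "inverse")

#: calibration predictor kind each variant requires
_VARIANT_MODEL_KIND = {"static": "linear", "dynamic": "linear", "inverse": "inverse"}


class ConfigurationError(ValueError):
    """Settings and calibration model are mutually inconsistent."""


@dataclass(frozen=True)
class AlgorithmSettings:
    """One point of the algorithm-adjustment space.

    ``window_length`` (n) and ``window_threshold`` (k) define the
    k-out-of-n rule; ``silent_min`` the post-trigger refractory period;
    ``decrease_mult`` the threshold margin in units of the calibration
    RMSSD standard deviation; the buffer lengths apply to the dynamic
    variant only.
    """

    variant: str = "static"
    window_length: int = 5
    window_threshold: int = 4
    silent_min: int = 20
    decrease_mult: float = 0.5
    hrv_buffer_min: int = 60
    aee_buffer_min: int = 40

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if not (2 <= self.window_length <= 30):
            raise ConfigurationError(
                f"window_length {self.window_length} outside [2, 30]"
            )
        if not (1 <= self.window_threshold <= self.window_length - 1):
            raise ConfigurationError(
                f"window_threshold {self.window_threshold} outside "
                f"[1, {self.window_length - 1}]"
            )
        if self.silent_min < 0:
            raise ConfigurationError("silent_min must be >= 0")
        if self.decrease_mult <= 0:
            raise ConfigurationError("decrease_mult must be > 0")
        if self.hrv_buffer_min < 1 or self.aee_buffer_min < 1:
            raise ConfigurationError("buffer lengths must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AlgorithmSettings":
        return cls(**d)

    @property
    def label(self) -> str:
        """Field-style "k out of n" label, e.g. ``10/7`` for 7-of-10."""
        return f"{self.window_length}/{self.window_threshold}"


@dataclass
class TriggerTrain:
    """Minute-level output of one algorithm run on one participant."""

    participant_id: str
    settings: AlgorithmSettings
    decrease_flags: np.ndarray  # bool per minute
    trigger_minutes: np.ndarray  # sorted int minute indices
    threshold_trace: np.ndarray  # ms per minute (NaN on unusable minutes)

    @property
    def n_triggers(self) -> int:
        return len(self.trigger_minutes)


def expected_rmssd(
    model: CalibrationModel,
    aee,
    dynamic_intercept=None,
) -> np.ndarray:
    """Metabolically expected RMSSD at the given AEE.

    With ``dynamic_intercept`` (scalar or per-minute array) the static
    intercept is replaced but the slope term is retained, so the dynamic
    prediction degenerates exactly to the static one when the buffer mean
    equals the static intercept.
    """
    x = model.predictor(aee)
    intercept = model.intercept if dynamic_intercept is None else dynamic_intercept
    return np.asarray(intercept, dtype=float) + model.slope * x


def run_dynamic_state(
    series: ParticipantSeries,
    model: CalibrationModel,
    settings: AlgorithmSettings,
) -> np.ndarray:
    """Per-minute dynamic intercept: mean of the lag-1 HRV ring buffer.

    The HRV buffer starts filled so its mean is the static intercept; the
    AEE buffer starts at the calibration-mean AEE.  At each minute the
    intercept is read first, then the buffers are updated: the HRV buffer
    receives the observed RMSSD only when the AEE buffer mean (the trailing
    activity level) is below the calibration mean, otherwise the static
    intercept; the AEE buffer always receives the minute's AEE.  Invalid
    minutes push the neutral values (intercept, calibration-mean AEE).
    """
    if model.predictor_kind != "linear":
        raise ConfigurationError("dynamic state requires a linear-kind model")
    n = series.duration_min
    trace = np.empty(n)
    hrv_buf = deque([model.intercept] * settings.hrv_buffer_min,
                    maxlen=settings.hrv_buffer_min)
    aee_buf = deque([model.mean_aee_cal] * settings.aee_buffer_min,
                    maxlen=settings.aee_buffer_min)
    hrv_sum = model.intercept * settings.hrv_buffer_min
    aee_sum = model.mean_aee_cal * settings.aee_buffer_min
    usable = series.usable()
    for t in range(n):
        trace[t] = hrv_sum / settings.hrv_buffer_min
        if usable[t]:
            if aee_sum / settings.aee_buffer_min < model.mean_aee_cal:
                hrv_push = float(series.rmssd[t])
            else:
                hrv_push = model.intercept
            aee_push = float(series.aee[t])
        else:
            hrv_push = model.intercept
            aee_push = model.mean_aee_cal
        hrv_sum += hrv_push - hrv_buf[0]
        hrv_buf.append(hrv_push)
        aee_sum += aee_push - aee_buf[0]
        aee_buf.append(aee_push)
    return trace


def flag_decreases(
    series: ParticipantSeries,
    model: CalibrationModel,
    settings: AlgorithmSettings,
    dynamic_intercept: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify each minute as meaningful RMSSD decrease or not.

    Returns ``(flags, threshold_trace)`` where the trace is the expected
    RMSSD minus the margin (the threshold line of the audit plots).
    Invalid minutes are flagged False and their trace is NaN.
    """
    if series.participant_id != model.participant_id:
        raise ConfigurationError(
            f"series {series.participant_id!r} vs model {model.participant_id!r}"
        )
    usable = series.usable()
    aee = np.where(usable, series.aee, np.nan)
    expected = expected_rmssd(model, aee, dynamic_intercept)
    threshold = expected - settings.decrease_mult * model.sd_rmssd_cal
    with np.errstate(invalid="ignore"):
        flags = usable & (series.rmssd < threshold)
    return flags, threshold


def run_algorithm(
    series: ParticipantSeries,
    model: CalibrationModel,
    settings: AlgorithmSettings,
) -> TriggerTrain:
    """Replay one AddHRVr algorithm over a participant-day.

    Strictly causal: minute ``t`` uses only minutes ``<= t``.  No trigger
    can fire before the first full window (``t >= window_length - 1``), and
    consecutive triggers are separated by strictly more than ``silent_min``
    minutes.
    """
    want = _VARIANT_MODEL_KIND[settings.variant]
    if model.predictor_kind != want:
        raise ConfigurationError(
            f"variant {settings.variant!r} requires a {want}-kind model, "
            f"got {model.predictor_kind!r}"
        )
    if settings.variant == "dynamic":
        dyn = run_dynamic_state(series, model, settings)
    else:
        dyn = None
    flags, trace = flag_decreases(series, model, settings, dynamic_intercept=dyn)
    trigger_minutes = scan_triggers(
        flags, settings.window_length, settings.window_threshold, settings.silent_min
    )
    return TriggerTrain(
        participant_id=series.participant_id,
        settings=settings,
        decrease_flags=flags,
        trigger_minutes=trigger_minutes,
        threshold_trace=trace,
    )


def window_counts(flags: np.ndarray, window_length: int) -> np.ndarray:
    """Trailing-window decrease counts; NaN-free, -1 before the first full window."""
    c = np.cumsum(np.concatenate(([0], flags.astype(int))))
    counts = np.full(len(flags), -1, dtype=int)
    if len(flags) >= window_length:
        counts[window_length - 1:] = c[window_length:] - c[:-window_length]
    return counts


def scan_triggers(
    flags: np.ndarray,
    window_length: int,
    window_threshold: int,
    silent_min: int,
) -> np.ndarray:
    """Greedy causal scan of the k-of-n rule with the silent period."""
    counts = window_counts(flags, window_length)
    candidates = np.flatnonzero(counts >= window_threshold)
    triggers: list[int] = []
    last = None
    for t in candidates:
        if last is None or t - last > silent_min:
            triggers.append(int(t))
            last = int(t)
    return np.asarray(triggers, dtype=int)


def enumerate_settings(
    min_len: int = 2, max_len: int = 30
) -> list[tuple[int, int]]:
    """All (window_length, window_threshold) pairs, lexicographically.

    Thresholds run 1..length-1 ("1 out of 2" up to "29 out of 30"); the
    full 2..30 range yields 435 adjustments.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    return [(n, k) for n in range(min_len, max_len + 1) for k in range(1, n)]


def train_to_frame(train: TriggerTrain) -> pd.DataFrame:
    """Minute-level export (minute, decrease_flag, threshold_trace, trigger)."""
    trigger = np.zeros(len(train.decrease_flags), dtype=int)
    trigger[train.trigger_minutes] = 1
    return pd.DataFrame(
        {
            "minute": np.arange(len(train.decrease_flags)),
            "decrease_flag": train.decrease_flags.astype(int),
            "threshold_trace": train.threshold_trace,
            "trigger": trigger,
        }
    )
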