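import numpy as np
import pytest

from addhrvr import (
    AlgorithmSettings,
    CalibrationModel,
    GeneratorParams,
    ParticipantSeries,
    fit_calibration,
    generate_cohort,
    screen_outliers,
)


def make_series(
    rmssd,
    aee=None,
    valid=None,
    stress=None,
    pid="T01",
) -> ParticipantSeries:
    rmssd = np.asarray(rmssd, dtype=float)
    n = len(rmssd)
    if aee is None:
        aee = np.full(n, 0.5)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return ParticipantSeries(
        participant_id=pid,
        rmssd=rmssd,
        aee=np.asarray(aee, dtype=float),
        valid=np.asarray(valid, dtype=bool),
        stress_level=None if stress is None else np.asarray(stress, dtype=float),
    )


def make_model(
    intercept=50.0,
    slope=-2.0,
    sd=10.0,
    mean_aee=0.7,
    pid="T01",
    kind="linear",
    epsilon=0.1,
) -> CalibrationModel:
    return CalibrationModel(
        participant_id=pid,
        predictor_kind=kind,
        intercept=intercept,
        slope=slope,
        pearson_r=-0.3,
        sd_rmssd_cal=sd,
        mean_aee_cal=mean_aee,
        epsilon=epsilon if kind == "inverse" else 0.0,
        n_used=100,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Six calibrated synthetic participants with a strong planted effect."""
    params = GeneratorParams(n_participants=6, effect_drop=15.0, seed=90)
    cohort = generate_cohort(params)
    out = []
    for series, truth in cohort:
        cleaned, n_removed = screen_outliers(series)
        model = fit_calibration(cleaned, n_removed=n_removed)
        out.append((cleaned, model, truth))
    return out


@pytest.fixture()
def default_settings():
    return AlgorithmSettings(variant="static", window_length=5, window_threshold=4)
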