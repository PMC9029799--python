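"""Synthetic firefighter-like participant-days with known ground truth.

Each generated day mimics the structure of a 24-h ambulatory recording in
an on-call occupational cohort:

* a semi-Markov schedule of objective stress levels (0 = routine station
  work, 1 = routine operation, 2 = emergency operation) with episode
  durations drawn from shifted geometric distributions floored at the
  minimum episode length, tuned so the stationary occupancy approximates
  the requested level shares;
* minute-level activity energy expenditure (AEE, kcal/min): a low resting
  baseline, elevated levels during operations, occasional exercise bouts
  during routine work, plus Gaussian noise;
* minute-level RMSSD built from a person-specific linear law
  ``intercept + slope * aee`` plus stationary AR(1) noise, with a
  controllable suppression (``effect_drop`` ms for ``effect_duration``
  minutes) after every *increase* of objective stress — the planted
  stress signature the trigger pipeline is supposed to detect;
* a small share of artifact-flagged (invalid) minutes.

Setting ``effect_drop=0`` yields an exact null: RMSSD is then, in law,
unrelated to the direction of stress transitions, which is what type-I
error calibration of the evaluation stage rests on.

Person-level intercepts and slopes are drawn from normal distributions
whose defaults correspond to a published ambulatory calibration cohort
(intercept 51.05 +/- 24.04 ms; slope -5.96 +/- 4.46 ms per 1000 kcal/24 h,
mapped to ms per kcal/min via 1 kcal/min = 1.44 x 1000 kcal/24 h; slopes
truncated negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .timeseries_io import ParticipantSeries

#: ms per (kcal/min) corresponding to 1 ms per (1000 kcal/24 h)
SLOPE_UNIT = 1.44

#: embedded transition probabilities of the stress-level chain
#: (row = from-level; columns = to-levels in order 0,1,2)
_CHAIN = np.array(
    [
        [0.0, 0.6, 0.4],
        [0.8, 0.0, 0.2],
        [0.85, 0.15, 0.0],
    ]
)
#: relative visit frequencies of the embedded chain (solved stationary flow)
_VISIT_FREQ = np.array([1.0, 0.680, 0.536])


@dataclass(frozen=True)
class GeneratorParams:
    """Population and schedule parameters of the synthetic cohort."""

    n_participants: int = 38
    duration_min: int = 1440
    intercept_mean: float = 51.05  # ms
    intercept_sd: float = 24.04
    slope_mean: float = -5.96 * SLOPE_UNIT  # ms per (kcal/min)
    slope_sd: float = 4.46 * SLOPE_UNIT
    resid_sd: float = 13.0  # ms, stationary SD of the AR(1) noise
    ar1_phi: float = 0.6
    aee_base: float = 0.42  # kcal/min at rest
    aee_burst: float = 0.8  # added kcal/min during routine operations
    aee_noise_sd: float = 0.45
    n_exercise_bouts: int = 4  # per day, during routine work
    bout_kcal: float = 2.5
    bout_min: int = 20
    p_levels: tuple[float, float, float] = (0.814, 0.112, 0.074)
    mean_routine_min: float = 270.0  # mean level-0 episode length
    episode_min: int = 20
    effect_drop: float = 10.0  # ms RMSSD suppression after a stress increase
    effect_duration: int = 15  # minutes
    invalid_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.intercept_sd, self.slope_sd, self.resid_sd,
               self.aee_noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if abs(sum(self.p_levels) - 1.0) > 1e-9 or min(self.p_levels) < 0:
            raise ValueError("p_levels must be a distribution over 3 levels")
        if self.episode_min < 20:
            raise ValueError("episode_min must be >= 20")
        if self.effect_drop < 0:
            raise ValueError("effect_drop must be >= 0")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must be in (-1, 1)")
        if self.duration_min < self.episode_min:
            raise ValueError(
                f"duration_min {self.duration_min} too short for episodes of "
                f">= {self.episode_min} min"
            )


@dataclass(frozen=True)
class GroundTruth:
    """All draws behind one generated participant."""

    participant_id: str
    intercept: float
    slope: float
    seed: int
    transition_minutes: tuple[int, ...]  # every schedule boundary
    increase_minutes: tuple[int, ...]  # boundaries where the level rose


def _episode_mean_durations(params: GeneratorParams) -> np.ndarray:
    """Per-level mean episode lengths matching the occupancy targets."""
    p = np.asarray(params.p_levels)
    d = np.empty(3)
    d[0] = params.mean_routine_min
    scale = _VISIT_FREQ[0] * d[0] / p[0]
    for lvl in (1, 2):
        d[lvl] = p[lvl] / _VISIT_FREQ[lvl] * scale if p[lvl] > 0 else 0.0
    return d


def _draw_duration(rng: np.random.Generator, mean: float, floor: int) -> int:
    """Shifted geometric episode length: floor + Geom, with the given mean."""
    if mean <= floor + 1:
        return floor
    p = 1.0 / (mean - floor + 1.0)
    return floor + int(rng.geometric(p)) - 1


def _stress_schedule(
    rng: np.random.Generator, params: GeneratorParams
) -> np.ndarray:
    n = params.duration_min
    if params.p_levels[1] + params.p_levels[2] == 0:
        return np.zeros(n, dtype=int)
    means = _episode_mean_durations(params)
    levels = np.empty(n, dtype=int)
    t = 0
    state = 0
    while t < n:
        dur = _draw_duration(rng, means[state], params.episode_min)
        levels[t : t + dur] = state
        t += dur
        state = int(rng.choice(3, p=_CHAIN[state]))
    return levels


def generate_participant(
    params: GeneratorParams,
    participant_seed: Union[int, np.random.SeedSequence],
    participant_id: str = "P00",
) -> tuple[ParticipantSeries, GroundTruth]:
    """Draw one participant-day and its ground truth."""
    if isinstance(participant_seed, np.random.SeedSequence):
        seed_repr = int(participant_seed.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(participant_seed)
    else:
        seed_repr = int(participant_seed)
        rng = np.random.default_rng(participant_seed)
    n = params.duration_min

    intercept = rng.normal(params.intercept_mean, params.intercept_sd)
    intercept = max(intercept, 15.0)  # RMSSD levels below ~15 ms are implausible
    slope = rng.normal(params.slope_mean, params.slope_sd)
    if params.slope_sd > 0:
        slope = min(slope, -0.5)  # HRV~movement slopes are negative in this cohort
    levels = _stress_schedule(rng, params)

    # AEE: level-dependent mean + exercise bouts during routine work + noise
    level_mean = np.array(
        [params.aee_base,
         params.aee_base + params.aee_burst,
         params.aee_base + 1.6 * params.aee_burst]
    )
    aee = level_mean[levels].astype(float)
    for _ in range(params.n_exercise_bouts):
        start = int(rng.integers(0, max(n - params.bout_min, 1)))
        bout = slice(start, start + params.bout_min)
        mask = levels[bout] == 0
        aee[bout][mask] += params.bout_kcal
    aee = aee + rng.normal(0.0, params.aee_noise_sd, size=n)
    aee = np.clip(aee, 0.02, None)

    # stationary AR(1) noise on RMSSD
    if params.resid_sd > 0:
        innov = rng.normal(
            0.0, params.resid_sd * np.sqrt(1.0 - params.ar1_phi**2), size=n
        )
        e0 = rng.normal(0.0, params.resid_sd)
        noise, _ = lfilter([1.0], [1.0, -params.ar1_phi], innov,
                           zi=np.array([params.ar1_phi * e0]))
    else:
        noise = np.zeros(n)

    rmssd = intercept + slope * aee + noise

    boundaries = np.flatnonzero(np.diff(levels) != 0) + 1
    increases = tuple(
        int(b) for b in boundaries if levels[b] > levels[b - 1]
    )
    for b in increases:
        rmssd[b : b + params.effect_duration] -= params.effect_drop
    rmssd = np.clip(rmssd, 1.0, None)

    valid = rng.random(n) >= params.invalid_rate

    series = ParticipantSeries(
        participant_id=participant_id,
        rmssd=rmssd,
        aee=aee,
        valid=valid,
        stress_level=levels.astype(float),
    )
    truth = GroundTruth(
        participant_id=participant_id,
        intercept=float(intercept),
        slope=float(slope),
        seed=seed_repr,
        transition_minutes=tuple(int(b) for b in boundaries),
        increase_minutes=increases,
    )
    return series, truth


def generate_cohort(
    params: GeneratorParams,
) -> list[tuple[ParticipantSeries, GroundTruth]]:
    """Draw ``n_participants`` independent days from the master seed."""
    children = np.random.SeedSequence(params.seed).spawn(params.n_participants)
    cohort = []
    for i, child in enumerate(children):
        pid = f"P{i + 1:02d}"
        cohort.append(generate_participant(params, child, participant_id=pid))
    return cohort


def ground_truth_to_frame(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    """Sidecar export of the generator's draws."""
    return pd.DataFrame(
        {
            "participant": [t.participant_id for t in truths],
            "intercept": [t.intercept for t in truths],
            "slope": [t.slope for t in truths],
            "seed": [t.seed for t in truths],
            "transition_minutes": [
                ";".join(str(m) for m in t.transition_minutes) for t in truths
            ],
            "increase_minutes": [
                ";".join(str(m) for m in t.increase_minutes) for t in truths
            ],
        }
    )
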