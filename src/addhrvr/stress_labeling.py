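"""Objective stress transitions and trigger matching.

Minute-level objective stress codes (0 = routine station work, 1 = routine
operation, 2 = emergency operation) are run-length encoded into episodes;
a *transition* is a boundary between two episodes that each last at least
``min_duration`` minutes (20 by default).  Transitions are coded 1 for an
increase of objective stress and 0 for a decrease.

Requiring the minimum duration on *both* flanking episodes is deliberately
conservative: it guarantees the follow windows of consecutive transitions
cannot nest, so each trigger is attributable to at most one transition.

A transition is *triggered* when at least one trigger fires in the
half-open follow window ``(t, t + follow_window]`` — a trigger at the
transition minute itself belongs to the preceding situation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .timeseries_io import ParticipantSeries
from .trigger_engine import TriggerTrain


@dataclass(frozen=True)
class Transition:
    """One boundary between qualifying stress episodes."""

    participant_id: str
    t_min: int  # first minute of the new level
    from_level: int
    to_level: int
    direction: int  # 1 = increase of objective stress, 0 = decrease

    def __post_init__(self) -> None:
        if self.from_level == self.to_level:
            raise ValueError("transition requires a level change")


@dataclass(frozen=True)
class EventRecord:
    """One transition paired with trigger presence in its follow window."""

    transition: Transition
    trigger_present: int  # 1 iff >= 1 trigger in (t, t + follow_window]
    settings_id: str = ""


@dataclass(frozen=True)
class MatchResult:
    events: tuple[EventRecord, ...]
    triggered_increases: int
    triggered_decreases: int


def detect_transitions(
    series: ParticipantSeries, min_duration: int = 20
) -> list[Transition]:
    """Run-length encode the stress-level series and emit qualifying boundaries.

    Both the preceding and the following episode must last at least
    ``min_duration`` minutes; a short episode therefore suppresses the
    boundaries on both of its sides.  Levels must be present on every
    minute of the series.
    """
    if series.stress_level is None:
        raise ValueError(f"{series.participant_id}: series has no stress levels")
    levels = series.stress_level
    missing = np.flatnonzero(~np.isfinite(levels))
    if missing.size:
        raise ValueError(
            f"{series.participant_id}: stress level missing at minute "
            f"{int(series.minute[missing[0]])}"
        )
    levels = levels.astype(int)
    n = len(levels)
    if n == 0:
        return []
    boundaries = np.flatnonzero(np.diff(levels) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    run_len = ends - starts
    out: list[Transition] = []
    for j in range(1, len(starts)):
        if run_len[j - 1] >= min_duration and run_len[j] >= min_duration:
            frm = int(levels[starts[j - 1]])
            to = int(levels[starts[j]])
            out.append(
                Transition(
                    participant_id=series.participant_id,
                    t_min=int(series.minute[starts[j]]),
                    from_level=frm,
                    to_level=to,
                    direction=int(to > frm),
                )
            )
    return out


def match_triggers(
    transitions: Sequence[Transition],
    train: TriggerTrain,
    follow_window: int = 20,
) -> MatchResult:
    """Pair each transition with trigger presence in ``(t, t+follow_window]``.

    Returns one event per transition plus the aggregate counts of triggered
    increases and decreases.
    """
    triggers = np.asarray(train.trigger_minutes)
    events = []
    inc = dec = 0
    for tr in transitions:
        if tr.participant_id != train.participant_id:
            raise ValueError(
                f"transition participant {tr.participant_id!r} does not match "
                f"train participant {train.participant_id!r}"
            )
        hit = int(
            np.any((triggers > tr.t_min) & (triggers <= tr.t_min + follow_window))
        )
        events.append(
            EventRecord(transition=tr, trigger_present=hit,
                        settings_id=train.settings.label)
        )
        if hit:
            if tr.direction == 1:
                inc += 1
            else:
                dec += 1
    return MatchResult(tuple(events), triggered_increases=inc, triggered_decreases=dec)


def events_to_frame(events: Sequence[EventRecord]) -> pd.DataFrame:
    """Flat export: participant, minute, levels, direction, trigger presence."""
    return pd.DataFrame(
        {
            "participant": [e.transition.participant_id for e in events],
            "minute": [e.transition.t_min for e in events],
            "from_level": [e.transition.from_level for e in events],
            "to_level": [e.transition.to_level for e in events],
            "direction": [e.transition.direction for e in events],
            "trigger_present": [e.trigger_present for e in events],
            "settings": [e.settings_id for e in events],
        }
    )
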