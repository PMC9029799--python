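"""Minute-level physiological time series: data model, CSV I/O, validation.

The canonical unit of data is one participant-day: a contiguous, 0-based
minute grid carrying vagally-mediated HRV (RMSSD, ms), activity energy
expenditure (AEE, kcal per minute), a validity flag (artifact screening),
and optionally an ordinal objective stress level (0 = routine station work,
1 = routine operation, 2 = emergency operation).

Gaps in the recording are represented explicitly as ``valid=False`` minutes,
never omitted, so that window arithmetic downstream is unambiguous.  Minute
``t`` covers the half-open interval ``[t, t+1)`` from recording start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: canonical CSV column names; a user-supplied dialect maps these onto
#: whatever the device export calls them.
CANONICAL_COLUMNS = ("minute", "rmssd_ms", "aee_kcal", "valid", "stress_level")


class FormatError(ValueError):
    """Malformed input file (duplicated minutes, unparseable structure)."""


@dataclass(frozen=True)
class MinuteRecord:
    """One 1-min segment of the recording."""

    t_min: int
    rmssd: Optional[float]  # ms, > 0 when present
    aee: Optional[float]  # kcal expended in this minute, >= 0 when present
    valid: bool
    stress_level: Optional[int] = None


@dataclass
class ParticipantSeries:
    """One participant's contiguous minute grid.

    ``rmssd`` and ``aee`` use NaN for missing values; ``valid=False``
    minutes are treated as missing by every downstream operation even if
    they carry a numeric value.  ``stress_level`` is None when the series
    has no objective stress coding.
    """

    participant_id: str
    rmssd: np.ndarray
    aee: np.ndarray
    valid: np.ndarray
    stress_level: Optional[np.ndarray] = None
    minute: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rmssd = np.asarray(self.rmssd, dtype=float)
        self.aee = np.asarray(self.aee, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.stress_level is not None:
            self.stress_level = np.asarray(self.stress_level, dtype=float)
        if self.minute is None:
            self.minute = np.arange(len(self.rmssd))
        else:
            self.minute = np.asarray(self.minute, dtype=int)

    @property
    def duration_min(self) -> int:
        return len(self.rmssd)

    def usable(self) -> np.ndarray:
        """Boolean mask of minutes usable for analysis (valid + both signals)."""
        return self.valid & np.isfinite(self.rmssd) & np.isfinite(self.aee)

    def records(self) -> Iterator[MinuteRecord]:
        for i in range(self.duration_min):
            lvl = None
            if self.stress_level is not None and np.isfinite(self.stress_level[i]):
                lvl = int(self.stress_level[i])
            yield MinuteRecord(
                t_min=int(self.minute[i]),
                rmssd=None if not np.isfinite(self.rmssd[i]) else float(self.rmssd[i]),
                aee=None if not np.isfinite(self.aee[i]) else float(self.aee[i]),
                valid=bool(self.valid[i]),
                stress_level=lvl,
            )

    def copy(self) -> "ParticipantSeries":
        return ParticipantSeries(
            participant_id=self.participant_id,
            rmssd=self.rmssd.copy(),
            aee=self.aee.copy(),
            valid=self.valid.copy(),
            stress_level=None if self.stress_level is None else self.stress_level.copy(),
            minute=self.minute.copy(),
        )


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_series`."""

    t_min: int
    rule: str
    detail: str = ""


def _coerce_numeric(values: pd.Series) -> np.ndarray:
    return pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)


def read_minute_series(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    participant_id: Optional[str] = None,
) -> ParticipantSeries:
    """Read one participant's minute series from CSV.

    Parameters
    ----------
    path
        CSV file with a header row.  Required columns (after applying
        ``dialect``): ``minute``, ``rmssd_ms``, ``aee_kcal``; optional:
        ``valid`` (0/1, default 1) and ``stress_level`` (0/1/2).
    dialect
        Mapping from canonical column names to the file's column names,
        e.g. ``{"rmssd_ms": "HRV_RMSSD"}``.  Unmapped names are used as-is.
    participant_id
        Defaults to the file stem.

    Notes
    -----
    Minute indices are normalised to a 0-based contiguous grid: the earliest
    minute becomes 0 and absent minutes become ``valid=False`` records.
    Rows with non-numeric or out-of-range physiology (RMSSD <= 0, AEE < 0)
    are kept on the grid but marked invalid.
    """
    try:
        frame = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read minute series from {path!r}: {exc}") from exc

    names = {c: c for c in CANONICAL_COLUMNS}
    if dialect:
        names.update(dialect)
    for required in ("minute", "rmssd_ms", "aee_kcal"):
        if names[required] not in frame.columns:
            raise FormatError(
                f"{path!r}: missing required column {names[required]!r}"
            )

    minutes = _coerce_numeric(frame[names["minute"]])
    if np.any(~np.isfinite(minutes)):
        raise FormatError(f"{path!r}: non-numeric minute index")
    minutes = minutes.astype(int)
    dup = pd.Series(minutes).duplicated()
    if dup.any():
        offending = int(minutes[dup.to_numpy()][0])
        raise FormatError(f"{path!r}: duplicated minute index {offending}")

    rmssd = _coerce_numeric(frame[names["rmssd_ms"]])
    aee = _coerce_numeric(frame[names["aee_kcal"]])
    if names["valid"] in frame.columns:
        valid = _coerce_numeric(frame[names["valid"]])
        valid = np.where(np.isfinite(valid), valid, 0).astype(bool)
    else:
        valid = np.ones(len(frame), dtype=bool)
    stress = None
    if names["stress_level"] in frame.columns:
        stress = _coerce_numeric(frame[names["stress_level"]])

    # out-of-range physiology invalidates the minute but keeps the grid slot
    bad = ~np.isfinite(rmssd) | (rmssd <= 0) | ~np.isfinite(aee) | (aee < 0)
    valid = valid & ~bad
    rmssd = np.where(np.isfinite(rmssd) & (rmssd > 0), rmssd, np.nan)
    aee = np.where(np.isfinite(aee) & (aee >= 0), aee, np.nan)

    # normalise to 0-based contiguous grid; absent minutes -> invalid slots
    minutes = minutes - minutes.min() if len(minutes) else minutes
    n = int(minutes.max()) + 1 if len(minutes) else 0
    g_rmssd = np.full(n, np.nan)
    g_aee = np.full(n, np.nan)
    g_valid = np.zeros(n, dtype=bool)
    g_stress = np.full(n, np.nan) if stress is not None else None
    g_rmssd[minutes] = rmssd
    g_aee[minutes] = aee
    g_valid[minutes] = valid
    if g_stress is not None:
        g_stress[minutes] = stress

    pid = participant_id
    if pid is None:
        import os

        pid = os.path.splitext(os.path.basename(str(path)))[0]
    return ParticipantSeries(
        participant_id=pid,
        rmssd=g_rmssd,
        aee=g_aee,
        valid=g_valid,
        stress_level=g_stress,
    )


def write_minute_series(series: ParticipantSeries, path) -> None:
    """Write a series to the canonical CSV dialect (round-trip stable).

    Missing values are written as empty fields and booleans as 0/1; the
    ``stress_level`` column is emitted only when the series carries one.
    """
    data = {
        "minute": series.minute,
        "rmssd_ms": series.rmssd,
        "aee_kcal": series.aee,
        "valid": series.valid.astype(int),
    }
    if series.stress_level is not None:
        lv = series.stress_level
        data["stress_level"] = pd.array(
            [None if not np.isfinite(v) else int(v) for v in lv], dtype="Int64"
        )
    frame = pd.DataFrame(data)
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write minute series to {path!r}: {exc}") from exc


def validate_series(series: ParticipantSeries) -> list[Violation]:
    """Check every type invariant; return one entry per violated rule.

    Reporting, not raising: an empty list means the series is compliant.
    """
    report: list[Violation] = []
    m = series.minute
    if len(m) != series.duration_min:
        report.append(Violation(-1, "duration", "minute grid length mismatch"))
    breaks = np.flatnonzero(np.diff(m) != 1)
    for b in breaks:
        report.append(
            Violation(int(m[b]), "contiguity", f"gap after minute {int(m[b])}")
        )
    if len(m) and m[0] != 0:
        report.append(Violation(int(m[0]), "origin", "grid does not start at 0"))
    for i in np.flatnonzero(np.isfinite(series.rmssd) & (series.rmssd <= 0)):
        report.append(Violation(int(m[i]), "rmssd_positive", f"rmssd={series.rmssd[i]}"))
    for i in np.flatnonzero(np.isfinite(series.aee) & (series.aee < 0)):
        report.append(Violation(int(m[i]), "aee_nonnegative", f"aee={series.aee[i]}"))
    if series.stress_level is not None:
        lv = series.stress_level
        ok = ~np.isfinite(lv) | np.isin(lv, (0.0, 1.0, 2.0))
        for i in np.flatnonzero(~ok):
            report.append(Violation(int(m[i]), "stress_level_range", f"level={lv[i]}"))
    return report
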