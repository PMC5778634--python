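"""Accelerometer count processing: intensity classification, non-wear
detection, wear time and the valid-day filter.

Counts are vertical-axis ActiGraph-style counts per 15 s epoch.  Intensity
is classified with the Evenson youth cutpoints defined at the 15 s epoch
length: sedentary <= 100 counts, light 101-2295, moderate 2296-4011,
vigorous >= 4012.  Non-wear is any maximal run of consecutive zero-count
epochs lasting at least 60 min (240 epochs); runs truncated by the
recording edge still count.  A day is valid when worn time reaches 9 h
(540 min); a participant is retained with at least one valid day.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IntensityClass",
    "WearSegment",
    "EVENSON_CUTPOINTS_15S",
    "classify_intensity",
    "detect_nonwear",
    "compute_wear_time",
    "select_valid",
    "intensity_minutes",
]

EPOCH_S = 15
#: Evenson cutpoints per 15 s epoch: upper bounds (inclusive) of
#: sedentary and light, lower bound of vigorous.
EVENSON_CUTPOINTS_15S = {"sedentary_max": 100, "light_max": 2295, "vigorous_min": 4012}

NONWEAR_MIN_DEFAULT = 60.0
VALID_DAY_MIN_DEFAULT = 540.0


class IntensityClass(enum.IntEnum):
    SEDENTARY = 0
    LIGHT = 1
    MODERATE = 2
    VIGOROUS = 3


#: Short column labels used throughout the per-class minute tables.
INTENSITY_LABELS = ("st", "lpa", "mpa", "vpa")


@dataclass(frozen=True)
class WearSegment:
    participant_id: str
    date: object
    start: pd.Timestamp
    end: pd.Timestamp
    status: str  # "worn" | "non-wear"

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


def classify_intensity(counts):
    """Map 15 s counts to :class:`IntensityClass` codes.

    Accepts a scalar or array; negative counts are rejected.  The four
    half-open bands partition [0, inf): SEDENTARY iff counts <= 100,
    LIGHT iff 100 < counts < 2296, MODERATE iff 2296 <= counts < 4012,
    VIGOROUS iff counts >= 4012.
    """
    arr = np.asarray(counts)
    if np.any(arr < 0):
        raise ValueError("negative accelerometer counts are not valid input")
    out = np.full(arr.shape, IntensityClass.SEDENTARY, dtype=np.int8)
    out[arr > EVENSON_CUTPOINTS_15S["sedentary_max"]] = IntensityClass.LIGHT
    out[arr > EVENSON_CUTPOINTS_15S["light_max"]] = IntensityClass.MODERATE
    out[arr >= EVENSON_CUTPOINTS_15S["vigorous_min"]] = IntensityClass.VIGOROUS
    if np.isscalar(counts) or arr.ndim == 0:
        return IntensityClass(int(out))
    return out


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zeros as (start, stop) index pairs, stop exclusive."""
    if len(counts) == 0:
        return []
    is_zero = np.asarray(counts) == 0
    padded = np.concatenate([[False], is_zero, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def detect_nonwear(
    epochs: pd.DataFrame, nonwear_min: float = NONWEAR_MIN_DEFAULT
) -> list[WearSegment]:
    """Segment one participant-day of 15 s epochs into worn / non-wear.

    ``epochs`` needs columns ``participant_id``, ``timestamp``, ``counts``
    sorted by timestamp (unsorted input is an error, not silently fixed).
    Any nonzero epoch interrupts a zero run: the rule carries no spike
    allowance.  Recording gaps (spacing > 15 s) also break runs, since a
    zero run must be a continuous period.
    """
    ts = epochs["timestamp"].to_numpy()
    if len(ts) > 1 and np.any(np.diff(ts) <= np.timedelta64(0, "s")):
        raise ValueError("count stream must be strictly increasing in time")
    counts = epochs["counts"].to_numpy()
    pid = epochs["participant_id"].iloc[0] if len(epochs) else ""

    # split the stream into contiguous bouts at recording gaps
    if len(ts) == 0:
        return []
    gap = np.diff(ts) > np.timedelta64(EPOCH_S, "s")
    bout_starts = np.concatenate([[0], np.flatnonzero(gap) + 1])
    bout_stops = np.concatenate([np.flatnonzero(gap) + 1, [len(ts)]])

    min_epochs = int(round(nonwear_min * 60 / EPOCH_S))
    segments: list[WearSegment] = []
    date = pd.Timestamp(ts[0]).date()

    def emit(i: int, j: int, status: str) -> None:
        if j > i:
            segments.append(
                WearSegment(
                    pid,
                    date,
                    pd.Timestamp(ts[i]),
                    pd.Timestamp(ts[j - 1]) + pd.Timedelta(seconds=EPOCH_S),
                    status,
                )
            )

    for b0, b1 in zip(bout_starts, bout_stops):
        runs = [
            (b0 + s, b0 + e)
            for s, e in _zero_runs(counts[b0:b1])
            if e - s >= min_epochs
        ]
        cursor = b0
        for s, e in runs:
            emit(cursor, s, "worn")
            emit(s, e, "non-wear")
            cursor = e
        emit(cursor, b1, "worn")
    return segments


def compute_wear_time(segments: list[WearSegment]) -> float:
    """Minutes worn, at quarter-minute (15 s epoch) resolution."""
    return sum(s.duration_min for s in segments if s.status == "worn")


def select_valid(
    wear_times: pd.DataFrame, valid_day_min: float = VALID_DAY_MIN_DEFAULT
) -> tuple[pd.DataFrame, set]:
    """Flag valid days (wear >= 540 min) and list included participants.

    ``wear_times`` has columns ``participant_id``, ``date``, ``wear_min``.
    Returns the same table with a boolean ``valid`` column, plus the set
    of participants having at least one valid day.
    """
    out = wear_times.copy()
    out["valid"] = out["wear_min"] >= valid_day_min
    included = set(out.loc[out["valid"], "participant_id"].unique())
    return out, included


def intensity_minutes(intensity_codes) -> dict[str, float]:
    """Minutes per intensity class from a vector of 15 s class codes."""
    codes = np.asarray(intensity_codes)
    return {
        label: 0.25 * float(np.sum(codes == cls))
        for label, cls in zip(INTENSITY_LABELS, IntensityClass)
    }
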