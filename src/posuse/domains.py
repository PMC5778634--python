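"""Domain assignment and segmentation of fused epochs.

Every located, worn epoch gets exactly one context label: transport
epochs keep their movement mode; stationary epochs are school (with a
physical-education / class / recess subclassification from the class
timetable) when within the 100 m school buffer during school hours on a
school day, otherwise home when within the 100 m home buffer, otherwise
leisure.  School takes precedence over home when buffers overlap during
school hours, being the more specific rule.  Maximal runs of identical
labels are then consolidated into events (stationary) and trips
(per-mode movement), the unit on which interview annotations and POS
attribution operate.  Buffer tests use great-circle distance, boundary
inclusive (<= 100 m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accel import INTENSITY_LABELS
from .fusion import STATIONARY, haversine_distance

__all__ = [
    "BUFFER_M",
    "Segment",
    "assign_domains",
    "consolidate",
    "join_annotations",
    "UNKNOWN_POS",
]

BUFFER_M = 100.0

HOME = "home"
SCHOOL_PE = "school_pe"
SCHOOL_CLASS = "school_class"
SCHOOL_RECESS = "school_recess"
LEISURE = "leisure"
TRANSPORT_PREFIX = "transport:"
UNKNOWN_POS = "unknown/non-POS"

SCHOOL_DOMAINS = (SCHOOL_PE, SCHOOL_CLASS, SCHOOL_RECESS)


@dataclass
class Segment:
    participant_id: str
    date: object
    start: pd.Timestamp
    end: pd.Timestamp
    kind: str                      # "event" | "trip"
    label: str                     # domain (events) or mode (trips)
    duration_min: float
    intensity_min: dict = field(default_factory=dict)  # st/lpa/mpa/vpa
    lat: float = np.nan            # median location of member epochs
    lon: float = np.nan
    pos_category: str | None = None
    company: tuple = ()
    reasons: tuple = ()
    activities: tuple = ()

    @property
    def mvpa_min(self) -> float:
        return self.intensity_min.get("mpa", 0.0) + self.intensity_min.get("vpa", 0.0)


def _minutes_in_blocks(ts: pd.Series, blocks) -> np.ndarray:
    """Boolean mask of timestamps falling in any (start, end) time block."""
    mask = np.zeros(len(ts), dtype=bool)
    tod = ts.dt.time
    for start, end in blocks:
        mask |= (tod >= start) & (tod < end)
    return mask


def assign_domains(
    fused: pd.DataFrame,
    home_lat: float,
    home_lon: float,
    school_lat: float,
    school_lon: float,
    timetable,
    buffer_m: float = BUFFER_M,
) -> pd.DataFrame:
    """Label located worn epochs of one participant-day.

    ``fused`` must carry ``timestamp``, ``lat``/``lon``, ``movement``,
    ``worn`` (bool) and ``located`` (bool) columns.  ``timetable`` is the
    participant's class :class:`~posuse.io_formats.ClassTimetable` (or
    None for no school).  Adds a ``domain`` column; epochs not worn or
    not located get a null label.
    """
    if np.isnan(home_lat) or np.isnan(home_lon):
        raise ValueError("participant has no home coordinates")
    out = fused.copy()
    domain = np.full(len(out), None, dtype=object)
    usable = out["worn"].to_numpy(dtype=bool) & out["located"].to_numpy(dtype=bool)

    movement = out["movement"].to_numpy(dtype=object)
    moving = usable & (movement != STATIONARY)
    for i in np.flatnonzero(moving):
        domain[i] = TRANSPORT_PREFIX + movement[i]

    stat = usable & (movement == STATIONARY)
    idx = np.flatnonzero(stat)
    if len(idx):
        lat = out["lat"].to_numpy(dtype=float)[idx]
        lon = out["lon"].to_numpy(dtype=float)[idx]
        ts = out["timestamp"].iloc[idx]
        d_home = haversine_distance(lat, lon, home_lat, home_lon)
        at_home = d_home <= buffer_m
        at_school = np.zeros(len(idx), dtype=bool)
        in_hours = np.zeros(len(idx), dtype=bool)
        in_pe = np.zeros(len(idx), dtype=bool)
        in_recess = np.zeros(len(idx), dtype=bool)
        if timetable is not None and not (np.isnan(school_lat) or np.isnan(school_lon)):
            d_school = haversine_distance(lat, lon, school_lat, school_lon)
            at_school = d_school <= buffer_m
            weekday = ts.dt.weekday
            for wd in weekday.unique():
                day_tt = timetable.weekdays.get(int(wd))
                if day_tt is None:
                    continue
                sel = (weekday == wd).to_numpy()
                in_hours |= sel & _minutes_in_blocks(ts, [day_tt.school_hours])
                in_pe |= sel & _minutes_in_blocks(ts, day_tt.pe_blocks)
                in_recess |= sel & _minutes_in_blocks(ts, day_tt.recess_blocks)
        school = at_school & in_hours
        lab = np.full(len(idx), LEISURE, dtype=object)
        lab[at_home] = HOME
        lab[school] = SCHOOL_CLASS
        lab[school & in_recess] = SCHOOL_RECESS
        lab[school & in_pe] = SCHOOL_PE
        domain[idx] = lab
    out["domain"] = domain
    return out


def consolidate(labelled: pd.DataFrame) -> list[Segment]:
    """Run-length encode labelled epochs of one participant-day into
    Segments.  Location-missing / non-worn epochs (null domain) break
    runs and belong to no segment.  Intensity minutes accumulate from
    the 15 s class codes carried on each fused epoch (0.25 min each)."""
    segs: list[Segment] = []
    if labelled.empty:
        return segs
    pid = labelled["participant_id"].iloc[0] if "participant_id" in labelled else ""
    dom = labelled["domain"].to_numpy(dtype=object)
    n = len(labelled)
    start = 0
    for i in range(1, n + 1):
        if i < n and dom[i] == dom[start]:
            continue
        label = dom[start]
        if label is not None:
            chunk = labelled.iloc[start:i]
            ts0 = chunk["timestamp"].iloc[0]
            ts1 = chunk["timestamp"].iloc[-1] + pd.Timedelta(seconds=30)
            codes = np.concatenate(
                [chunk["intensity_0"].to_numpy(), chunk["intensity_1"].to_numpy()]
            )
            imin = {
                k: 0.25 * float(np.sum(codes == c))
                for c, k in enumerate(INTENSITY_LABELS)
            }
            if label.startswith(TRANSPORT_PREFIX):
                kind, seg_label = "trip", label[len(TRANSPORT_PREFIX):]
            else:
                kind, seg_label = "event", label
            segs.append(
                Segment(
                    participant_id=pid,
                    date=ts0.date(),
                    start=ts0,
                    end=ts1,
                    kind=kind,
                    label=seg_label,
                    duration_min=0.5 * len(chunk),
                    intensity_min=imin,
                    lat=float(np.nanmedian(chunk["lat"].to_numpy(dtype=float))),
                    lon=float(np.nanmedian(chunk["lon"].to_numpy(dtype=float))),
                )
            )
        start = i
    return segs


def join_annotations(segments: list[Segment], annotations: pd.DataFrame) -> list[Segment]:
    """Attach interview annotations to leisure events by window overlap.

    Each annotation row (participant_id, start, end, pos_category,
    company, reasons, activities) goes to the leisure event with maximal
    temporal overlap; ties break to the earlier event; zero overlap
    leaves the annotation unused with a warning.  Leisure events that
    receive no annotation keep the category "unknown/non-POS".
    """
    for seg in segments:
        if seg.kind == "event" and seg.label == LEISURE and seg.pos_category is None:
            seg.pos_category = UNKNOWN_POS
    leisure = [s for s in segments if s.kind == "event" and s.label == LEISURE]
    if annotations is None or len(annotations) == 0:
        return segments
    for _, ann in annotations.iterrows():
        best, best_ov = None, 0.0
        for seg in leisure:
            if seg.participant_id != ann["participant_id"]:
                continue
            ov = (
                min(seg.end, ann["end"]) - max(seg.start, ann["start"])
            ).total_seconds()
            if ov > best_ov:
                best, best_ov = seg, ov
        if best is None:
            warnings.warn(
                f"annotation {ann['participant_id']} {ann['start']} overlaps no leisure event"
            )
            continue
        best.pos_category = ann["pos_category"]
        best.company = tuple(ann.get("company", ()))
        best.reasons = tuple(ann.get("reasons", ()))
        best.activities = tuple(ann.get("activities", ()))
    return segments
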