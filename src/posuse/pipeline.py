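"""End-to-end orchestration: raw streams to participant summaries.

Stages, mirroring the processing chain the package implements:

1. count stream -> intensity classes, non-wear segmentation, wear time
   and the valid-day / included-participant filter (9 h rule);
2. GPS stream -> plausibility flags (per participant-day, since days
   split at midnight) and 30 s fusion with the count stream;
3. speeds, movement bands, optional interview corrections;
4. home / school / leisure domain labels, consolidation into events and
   trips, annotation join;
5. POS-visit extraction with trip attribution and per-participant
   aggregation over valid days.

Wear time and intensity totals depend only on the accelerometer: GPS
dropout or invalid fixes never change them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import accel, domains, fusion, visits as visits_mod
from .accel import classify_intensity
from .io_formats import (
    read_annotations,
    read_cohort,
    read_count_log,
    read_gps_log,
    read_schools,
    read_timetables,
    read_weather,
)

__all__ = ["PipelineResult", "process_dataset", "process_directory"]


@dataclass
class PipelineResult:
    summaries: pd.DataFrame
    visits: list
    segments: list
    wear: pd.DataFrame            # participant_id, date, wear_min, valid
    included: set
    descriptives: dict = field(default_factory=dict)
    day_tables: dict = field(default_factory=dict)  # pid -> per-day entries


def _day_intensity(counts_day: pd.DataFrame, worn: np.ndarray) -> dict:
    codes = classify_intensity(counts_day["counts"].to_numpy())
    return {
        k: 0.25 * float(np.sum((codes == c) & worn))
        for c, k in enumerate(accel.INTENSITY_LABELS)
    }


def process_dataset(
    gps: pd.DataFrame,
    counts: pd.DataFrame,
    cohort: pd.DataFrame,
    schools: pd.DataFrame,
    timetables: dict,
    annotations: pd.DataFrame,
    weather: pd.DataFrame | None = None,
    corrections: pd.DataFrame | None = None,
    nonwear_min: float = accel.NONWEAR_MIN_DEFAULT,
    valid_day_min: float = accel.VALID_DAY_MIN_DEFAULT,
    smooth_epochs: int = 1,
    max_speed_kmh: float = fusion.MAX_SPEED_KMH,
    max_jump_m: float = fusion.MAX_JUMP_M,
    max_elev_m: float = fusion.MAX_ELEV_M,
    keep_fused: bool = False,
) -> PipelineResult:
    """Run the full processing chain on in-memory tables."""
    schools_by_id = {r["school_id"]: r for _, r in schools.iterrows()}
    gps_by_pid = dict(tuple(gps.groupby("participant_id"))) if len(gps) else {}
    counts_by_pid = dict(tuple(counts.groupby("participant_id"))) if len(counts) else {}
    ann_by_pid = (
        dict(tuple(annotations.groupby("participant_id"))) if len(annotations) else {}
    )

    wear_rows = []
    all_segments: list = []
    all_visits: list = []
    day_tables: dict[str, list[dict]] = {}

    for _, participant in cohort.iterrows():
        pid = participant["participant_id"]
        if pid not in counts_by_pid:
            continue
        cts_p = counts_by_pid[pid]
        gps_p = gps_by_pid.get(
            pid, pd.DataFrame(columns=["participant_id", "timestamp", "lat", "lon", "elevation_m"])
        )
        timetable = timetables.get(participant.get("class_id"))
        school = schools_by_id.get(participant.get("school_id"))
        school_lat = float(school["lat"]) if school is not None else np.nan
        school_lon = float(school["lon"]) if school is not None else np.nan

        for date, cts_day in cts_p.groupby(cts_p["timestamp"].dt.date):
            segments_wear = accel.detect_nonwear(cts_day, nonwear_min=nonwear_min)
            wear_min = accel.compute_wear_time(segments_wear)
            wear_rows.append({"participant_id": pid, "date": date, "wear_min": wear_min})

            worn = np.zeros(len(cts_day), dtype=bool)
            ts = cts_day["timestamp"].to_numpy()
            for seg in segments_wear:
                if seg.status == "worn":
                    worn |= (ts >= np.datetime64(seg.start)) & (ts < np.datetime64(seg.end))

            gps_day = (
                gps_p[gps_p["timestamp"].dt.date == date] if len(gps_p) else gps_p
            )
            fused = fusion.align_streams(gps_day, cts_day)
            if fused.empty:
                day_tables.setdefault(pid, []).append(
                    {
                        "date": date,
                        "wear_min": wear_min,
                        "intensity_min": _day_intensity(cts_day, worn),
                        "visits": [],
                        "segments": [],
                        "_valid": wear_min >= valid_day_min,
                    }
                )
                continue
            located_fixes = fused.loc[fused["has_fix"]]
            valid = fusion.flag_invalid_fixes(
                located_fixes,
                max_speed_kmh=max_speed_kmh,
                max_jump_m=max_jump_m,
                max_elev_m=max_elev_m,
            )
            fused = fusion.add_movement(fused, valid)
            fused["movement"] = fusion.smooth_movement(
                fused["movement"].to_numpy(object), smooth_epochs
            )
            fused["participant_id"] = pid
            if corrections is not None and len(corrections):
                fused = fusion.apply_corrections(fused, corrections)

            # a fused epoch is worn when any of its 15 s counts is worn
            worn_by_ts = pd.Series(worn, index=cts_day["timestamp"])
            w0 = worn_by_ts.reindex(fused["timestamp"]).fillna(False).to_numpy(bool)
            w1 = (
                worn_by_ts.reindex(fused["timestamp"] + pd.Timedelta(seconds=15))
                .fillna(False)
                .to_numpy(bool)
            )
            fused["worn"] = w0 | w1
            # mask non-worn 15 s codes so they never enter intensity totals
            for j, wj in ((0, w0), (1, w1)):
                col = fused[f"intensity_{j}"].to_numpy().copy()
                col[~wj] = -1
                fused[f"intensity_{j}"] = col
            fused["located"] = fused["has_fix"] & fused["valid_fix"]

            fused = domains.assign_domains(
                fused,
                float(participant["home_lat"]),
                float(participant["home_lon"]),
                school_lat,
                school_lon,
                timetable,
            )
            segs = domains.consolidate(fused)
            ann_p = ann_by_pid.get(pid)
            if ann_p is not None:
                ann_day = ann_p[ann_p["start"].dt.date == date]
            else:
                ann_day = None
            segs = domains.join_annotations(segs, ann_day)
            day_visits = visits_mod.extract_pos_visits(segs)
            all_segments.extend(segs)
            all_visits.extend(day_visits)
            entry = {
                "date": date,
                "wear_min": wear_min,
                "intensity_min": _day_intensity(cts_day, worn),
                "visits": day_visits,
                "segments": segs,
                "_valid": wear_min >= valid_day_min,
            }
            if keep_fused:
                entry["fused"] = fused
            day_tables.setdefault(pid, []).append(entry)

    wear = pd.DataFrame(wear_rows, columns=["participant_id", "date", "wear_min"])
    wear, included = accel.select_valid(wear, valid_day_min=valid_day_min)

    rows = []
    kept_visits = []
    for _, participant in cohort.iterrows():
        pid = participant["participant_id"]
        if pid not in included:
            continue
        valid_days = [d for d in day_tables.get(pid, []) if d["_valid"]]
        if not valid_days:
            continue
        rows.append(visits_mod.summarize_participant(participant, valid_days, weather))
        for d in valid_days:
            kept_visits.extend(d["visits"])
    summaries = pd.DataFrame(rows)
    result = PipelineResult(
        summaries=summaries,
        visits=kept_visits,
        segments=all_segments,
        wear=wear,
        included=included,
        day_tables=day_tables,
    )
    if len(summaries):
        result.descriptives = visits_mod.cohort_descriptives(summaries, kept_visits)
    return result


def process_directory(directory, **kw) -> PipelineResult:
    """Read the canonical file set from a directory and process it.

    Ground-truth files (``ground_truth*``) are never read here: the
    pipeline consumes only the six measurement streams.
    """
    from pathlib import Path

    d = Path(directory)
    weather_path = d / "weather.csv"
    return process_dataset(
        gps=read_gps_log(d / "gps.csv"),
        counts=read_count_log(d / "counts.csv"),
        cohort=read_cohort(d / "cohort.csv"),
        schools=read_schools(d / "schools.csv"),
        timetables=read_timetables(d / "timetables.yaml"),
        annotations=read_annotations(d / "annotations.csv"),
        weather=read_weather(weather_path) if weather_path.exists() else None,
        **kw,
    )
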