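"""File formats: strict readers and writers for every pipeline stream.

One canonical CSV dialect per stream (UTF-8, comma separated, ISO-8601
local timestamps without zone offset — the study is single-city and a
config key names the timezone).  GPX 1.1 trackpoints are accepted as an
alternative GPS input.  Loading never silently drops rows: anything
that does not validate raises :class:`ValidationError` with enough
context to find the offending row.
"""

from __future__ import annotations

import datetime as dt
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "DayTimetable",
    "ClassTimetable",
    "read_gps_log",
    "read_gpx",
    "read_count_log",
    "read_cohort",
    "read_schools",
    "read_timetables",
    "read_annotations",
    "read_weather",
    "write_gps_log",
    "write_count_log",
    "write_cohort",
    "write_schools",
    "write_timetables",
    "write_annotations",
    "write_weather",
    "CATEGORICAL_LEVELS",
]


class ValidationError(ValueError):
    """An input file violated the dialect or a domain invariant."""


CATEGORICAL_LEVELS = {
    "gender": ("male", "female"),
    "ethnicity": ("western-European", "non-western-European"),
    "education": ("general", "technical", "vocational"),
    "ses": ("low", "high"),
    "sport_club": ("yes", "no"),
    "residence": ("rural", "suburban", "urban"),
}

GPS_COLUMNS = ["participant_id", "timestamp", "lat", "lon", "elevation_m"]
COUNT_COLUMNS = ["participant_id", "timestamp", "counts"]
LIST_SEP = ";"


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _check_monotone(df: pd.DataFrame, path) -> None:
    for pid, grp in df.groupby("participant_id", sort=False):
        ts = grp["timestamp"]
        dup = ts[ts.duplicated()]
        if len(dup):
            raise ValidationError(
                f"{path}: duplicate timestamp {dup.iloc[0]} for participant {pid}"
            )


def read_gps_log(path) -> pd.DataFrame:
    """Read a GPS fix log CSV: participant_id,timestamp,lat,lon,elevation_m.

    Rows are returned sorted by participant then timestamp.  Duplicate
    timestamps per participant, unparseable rows and out-of-range
    coordinates raise :class:`ValidationError`.  Elevation may be empty
    (missing) and is propagated as NaN.
    """
    df = pd.read_csv(path)
    _require_columns(df, GPS_COLUMNS[:4], path)
    if "elevation_m" not in df.columns:
        df["elevation_m"] = np.nan
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable timestamp ({exc})") from exc
    bad = df.index[(df["lat"].abs() > 90) | (df["lon"].abs() > 180)]
    if len(bad):
        raise ValidationError(
            f"{path}: coordinate out of range at data line {bad[0] + 2}"
        )
    if df[["lat", "lon"]].isna().any().any():
        raise ValidationError(f"{path}: missing coordinate")
    _check_monotone(df, path)
    return df.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)


def read_gpx(path, participant_id: str) -> pd.DataFrame:
    """Read GPX 1.1 trackpoints into the same frame as :func:`read_gps_log`.

    Timestamps are taken as local civil time (a trailing ``Z`` is
    stripped rather than converted: the canonical CSV dialect is
    zone-naive).
    """
    tree = ET.parse(path)
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    rows = []
    for pt in tree.getroot().iter("{http://www.topografix.com/GPX/1/1}trkpt"):
        ele = pt.find("gpx:ele", ns)
        time = pt.find("gpx:time", ns)
        if time is None or time.text is None:
            raise ValidationError(f"{path}: trackpoint without <time>")
        rows.append(
            {
                "participant_id": participant_id,
                "timestamp": pd.Timestamp(time.text.rstrip("Z")),
                "lat": float(pt.attrib["lat"]),
                "lon": float(pt.attrib["lon"]),
                "elevation_m": float(ele.text) if ele is not None else np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=GPS_COLUMNS)
    if len(df) and (df["lat"].abs().max() > 90 or df["lon"].abs().max() > 180):
        raise ValidationError(f"{path}: coordinate out of range")
    _check_monotone(df, path)
    return df.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)


def read_count_log(path) -> pd.DataFrame:
    """Read a 15 s count log CSV: participant_id,timestamp,counts."""
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, path)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable timestamp ({exc})") from exc
    if df["counts"].isna().any():
        raise ValidationError(f"{path}: missing counts value")
    if (df["counts"] < 0).any():
        line = int(df.index[df["counts"] < 0][0]) + 2
        raise ValidationError(f"{path}: negative counts at data line {line}")
    df["counts"] = df["counts"].astype(np.int64)
    _check_monotone(df, path)
    df = df.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)
    import warnings as _warnings

    for pid, grp in df.groupby("participant_id", sort=False):
        gaps = grp["timestamp"].diff().dropna()
        # spacing other than 15 s within a bout; breaks of 10 min or more
        # count as a new recording bout, not a mid-bout violation
        irregular = gaps[(gaps != pd.Timedelta(seconds=15)) & (gaps < pd.Timedelta(minutes=10))]
        if len(irregular):
            _warnings.warn(
                f"{path}: participant {pid} has {len(irregular)} irregular 15 s "
                "spacings; gaps are treated as missing epochs downstream"
            )
    return df


def _check_levels(df: pd.DataFrame, path) -> None:
    for col, levels in CATEGORICAL_LEVELS.items():
        if col not in df.columns:
            continue
        bad = set(df[col].dropna().unique()) - set(levels)
        if bad:
            raise ValidationError(
                f"{path}: unknown level(s) {sorted(bad)} in column {col!r}; "
                f"allowed levels are {list(levels)}"
            )


def read_cohort(path) -> pd.DataFrame:
    """Read the cohort (demographics) table with categorical validation."""
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["participant_id", "age", "gender", "ethnicity", "education", "ses",
         "sport_club", "residence", "home_lat", "home_lon", "school_id", "class_id"],
        path,
    )
    _check_levels(df, path)
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def read_schools(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["school_id", "lat", "lon"], path)
    return df


@dataclass
class DayTimetable:
    school_hours: tuple  # (datetime.time, datetime.time)
    pe_blocks: list = field(default_factory=list)
    recess_blocks: list = field(default_factory=list)


@dataclass
class ClassTimetable:
    school_id: str
    class_id: str
    weekdays: dict = field(default_factory=dict)  # weekday int -> DayTimetable


def _parse_time(s) -> dt.time:
    return dt.time.fromisoformat(str(s))


def _parse_block(b) -> tuple:
    return (_parse_time(b[0]), _parse_time(b[1]))


def read_timetables(path) -> dict[str, ClassTimetable]:
    """Read per-class timetables from YAML, keyed by class_id.

    PE and recess blocks must nest inside school hours and must not
    overlap each other.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, ClassTimetable] = {}
    for entry in raw:
        tt = ClassTimetable(str(entry["school_id"]), str(entry["class_id"]))
        for wd, day in entry.get("weekdays", {}).items():
            hours = _parse_block(day["school_hours"])
            pe = [_parse_block(b) for b in day.get("pe", [])]
            recess = [_parse_block(b) for b in day.get("recess", [])]
            for name, blocks in (("pe", pe), ("recess", recess)):
                for b in blocks:
                    if not (hours[0] <= b[0] < b[1] <= hours[1]):
                        raise ValidationError(
                            f"{path}: {name} block {b} outside school hours "
                            f"{hours} for class {tt.class_id}"
                        )
            blocks = sorted(pe + recess)
            for a, b in zip(blocks, blocks[1:]):
                if b[0] < a[1]:
                    raise ValidationError(
                        f"{path}: overlapping blocks {a} and {b} for class {tt.class_id}"
                    )
            tt.weekdays[int(wd)] = DayTimetable(hours, pe, recess)
        out[tt.class_id] = tt
    return out


def _split_list(val) -> tuple:
    if pd.isna(val) or val == "":
        return ()
    return tuple(x for x in str(val).split(LIST_SEP) if x)


def read_annotations(path) -> pd.DataFrame:
    """Read the POS annotation table (the interview's data product)."""
    from .visits import POS_CATEGORIES

    df = pd.read_csv(path)
    _require_columns(
        df, ["participant_id", "start", "end", "pos_category", "company"], path
    )
    df["participant_id"] = df["participant_id"].astype(str)
    df["start"] = pd.to_datetime(df["start"], format="ISO8601")
    df["end"] = pd.to_datetime(df["end"], format="ISO8601")
    bad = set(df["pos_category"].dropna().unique()) - set(POS_CATEGORIES)
    if bad:
        raise ValidationError(
            f"{path}: unknown POS categories {sorted(bad)}; allowed: {list(POS_CATEGORIES)}"
        )
    for col in ("company", "reasons", "activities"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].map(_split_list)
    empty = df.index[df["company"].map(len) == 0]
    if len(empty):
        raise ValidationError(
            f"{path}: annotation with empty company at data line {empty[0] + 2}"
        )
    return df


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["date", "rain_mm", "sun_min", "temp_c"], path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if (df["rain_mm"] < 0).any() or (df["sun_min"] < 0).any():
        raise ValidationError(f"{path}: negative rain or sunshine")
    return df


# --- writers ------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path, timestamp_cols=()) -> None:
    out = df.copy()
    for col in timestamp_cols:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_gps_log(df: pd.DataFrame, path) -> None:
    _write_csv(df[GPS_COLUMNS], path, timestamp_cols=["timestamp"])


def write_count_log(df: pd.DataFrame, path) -> None:
    _write_csv(df[COUNT_COLUMNS], path, timestamp_cols=["timestamp"])


def write_cohort(df: pd.DataFrame, path) -> None:
    _write_csv(df, path)


def write_schools(df: pd.DataFrame, path) -> None:
    _write_csv(df, path)


def write_timetables(timetables: dict[str, ClassTimetable], path) -> None:
    entries = []
    for tt in timetables.values():
        wd = {}
        for day, d in sorted(tt.weekdays.items()):
            wd[day] = {
                "school_hours": [t.isoformat("minutes") for t in d.school_hours],
                "pe": [[a.isoformat("minutes"), b.isoformat("minutes")] for a, b in d.pe_blocks],
                "recess": [
                    [a.isoformat("minutes"), b.isoformat("minutes")] for a, b in d.recess_blocks
                ],
            }
        entries.append({"school_id": tt.school_id, "class_id": tt.class_id, "weekdays": wd})
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=True)


def write_annotations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("company", "reasons", "activities"):
        if col in out.columns:
            out[col] = out[col].map(lambda xs: LIST_SEP.join(xs))
    _write_csv(out, path, timestamp_cols=["start", "end"])


def write_weather(df: pd.DataFrame, path) -> None:
    _write_csv(df, path)
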