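"""GPS / accelerometer fusion on a 30 s grid.

Each GPS fix (one per 30 s) anchors a fused epoch that carries the two
15 s count epochs falling inside [fix, fix + 30 s).  Implausible fixes
are flagged with the three plausibility thresholds applied between a fix
and the last valid fix: speed above 130 km/h, displacement above 1 km,
or an elevation change above 100 m.  Epoch speed (from the last valid
fix, over the actual elapsed time) is banded into stationary (< 1 km/h),
pedestrian ([1, 10)), bicycle ([10, 25)) and motorized (>= 25 km/h)
movement.  Spatial validity never feeds back into wear time or intensity
totals: those are accelerometer-only quantities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .accel import classify_intensity

__all__ = [
    "EARTH_RADIUS_M",
    "MAX_SPEED_KMH",
    "MAX_JUMP_M",
    "MAX_ELEV_M",
    "SPEED_BANDS_KMH",
    "haversine_distance",
    "compute_speed",
    "classify_movement",
    "flag_invalid_fixes",
    "align_streams",
    "add_movement",
    "smooth_movement",
    "apply_corrections",
]

EARTH_RADIUS_M = 6_371_000.0

MAX_SPEED_KMH = 130.0
MAX_JUMP_M = 1000.0
MAX_ELEV_M = 100.0

#: Lower band edges in km/h: stationary below 1, then pedestrian,
#: bicycle from 10, motorized from 25.
SPEED_BANDS_KMH = {"pedestrian": 1.0, "bicycle": 10.0, "motorized": 25.0}

STATIONARY = "stationary"
MOVEMENT_LEVELS = (STATIONARY, "pedestrian", "bicycle", "motorized")

MATCH_TOLERANCE_S = 5.0
GRID_S = 30


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("coordinates outside WGS84 range")


def haversine_distance(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres on a sphere of radius 6371 km."""
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def compute_speed(distance_m, elapsed_s):
    """Speed in km/h over the actual elapsed time (>= one epoch)."""
    elapsed = np.asarray(elapsed_s, dtype=float)
    if np.any(elapsed <= 0):
        raise ValueError("elapsed time between fixes must be positive")
    return np.asarray(distance_m, dtype=float) / elapsed * 3.6


def classify_movement(speed_kmh):
    """Band a speed (km/h) into one of the four movement states."""
    speed = np.asarray(speed_kmh, dtype=float)
    out = np.full(speed.shape, STATIONARY, dtype=object)
    out[speed >= SPEED_BANDS_KMH["pedestrian"]] = "pedestrian"
    out[speed >= SPEED_BANDS_KMH["bicycle"]] = "bicycle"
    out[speed >= SPEED_BANDS_KMH["motorized"]] = "motorized"
    if np.ndim(speed_kmh) == 0:
        return str(out[()])
    return out


def flag_invalid_fixes(
    fixes: pd.DataFrame,
    max_speed_kmh: float = MAX_SPEED_KMH,
    max_jump_m: float = MAX_JUMP_M,
    max_elev_m: float = MAX_ELEV_M,
) -> np.ndarray:
    """Boolean valid flags for one participant's time-sorted fixes.

    A fix is invalid when, relative to the last *valid* fix, speed
    exceeds 130 km/h, displacement exceeds 1000 m, or the elevation
    change exceeds 100 m in absolute value; the chain then restarts from
    that last valid fix.  A missing elevation on either side skips the
    elevation test.  The first fix is valid by definition.
    """
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    elev = (
        fixes["elevation_m"].to_numpy(dtype=float)
        if "elevation_m" in fixes
        else np.full(len(fixes), np.nan)
    )
    ts = fixes["timestamp"].to_numpy()
    _check_coords(lat, lon)
    n = len(fixes)
    valid = np.ones(n, dtype=bool)
    if n == 0:
        return valid
    last = 0
    for i in range(1, n):
        dist = float(haversine_distance(lat[last], lon[last], lat[i], lon[i]))
        dt = (ts[i] - ts[last]) / np.timedelta64(1, "s")
        speed = dist / dt * 3.6 if dt > 0 else np.inf
        delev = abs(elev[i] - elev[last])
        bad = speed > max_speed_kmh or dist > max_jump_m
        if not np.isnan(delev):
            bad = bad or delev > max_elev_m
        if bad:
            valid[i] = False
        else:
            last = i
    return valid


def align_streams(
    gps: pd.DataFrame,
    counts: pd.DataFrame,
    tolerance_s: float = MATCH_TOLERANCE_S,
) -> pd.DataFrame:
    """Fuse one participant's GPS fixes and 15 s count epochs.

    Returns one row per 30 s slot with columns ``timestamp`` (slot
    anchor), ``lat``/``lon``/``elevation_m`` (NaN when no fix), ``has_fix``,
    ``counts_0``/``counts_1`` (the two 15 s counts, NaN when dropped),
    ``n_counts``, ``counts_30s`` and ``intensity_0``/``intensity_1``
    (15 s class codes, -1 when missing).  Count epochs that match no fix
    within tolerance become location-missing rows anchored on their 30 s
    grid slot: they keep contributing to wear and intensity totals but
    never to spatial domains.
    """
    if gps.empty and counts.empty:
        return pd.DataFrame(
            columns=[
                "timestamp", "lat", "lon", "elevation_m", "has_fix",
                "counts_0", "counts_1", "n_counts", "counts_30s",
                "intensity_0", "intensity_1",
            ]
        )
    tol = pd.Timedelta(seconds=tolerance_s)
    cts = counts.sort_values("timestamp").reset_index(drop=True)
    cts = cts.assign(_cidx=np.arange(len(cts)))
    matched = np.zeros(len(cts), dtype=bool)

    g = gps.sort_values("timestamp").reset_index(drop=True)
    if "elevation_m" not in g.columns:
        g = g.assign(elevation_m=np.nan)
    fused = g[["timestamp", "lat", "lon", "elevation_m"]].copy()
    fused["has_fix"] = True
    for j, offset in enumerate((0, 15)):
        probe = pd.DataFrame({"target": g["timestamp"] + pd.Timedelta(seconds=offset)})
        m = pd.merge_asof(
            probe,
            cts.rename(columns={"timestamp": "_cts"}),
            left_on="target",
            right_on="_cts",
            direction="nearest",
            tolerance=tol,
        )
        fused[f"counts_{j}"] = m["counts"].to_numpy(dtype=float)
        hit = m["_cidx"].dropna().astype(int).to_numpy()
        matched[hit] = True

    # leftover worn count epochs -> location-missing 30 s slots
    leftovers = cts.loc[~matched]
    if not leftovers.empty:
        slot = leftovers["timestamp"].dt.floor(f"{GRID_S}s")
        pos = (
            ((leftovers["timestamp"] - slot).dt.total_seconds() // 15)
            .clip(0, 1)
            .astype(int)
        )
        piv = leftovers.assign(_slot=slot, _pos=pos).pivot_table(
            index="_slot", columns="_pos", values="counts", aggfunc="first"
        )
        extra = pd.DataFrame(
            {
                "timestamp": piv.index,
                "lat": np.nan,
                "lon": np.nan,
                "elevation_m": np.nan,
                "has_fix": False,
                "counts_0": piv[0].to_numpy() if 0 in piv.columns else np.nan,
                "counts_1": piv[1].to_numpy() if 1 in piv.columns else np.nan,
            }
        )
        fused = pd.concat([fused, extra], ignore_index=True)

    fused = fused.sort_values("timestamp").reset_index(drop=True)
    if fused.empty:
        warnings.warn("empty overlap between GPS and count streams")
    cnt = fused[["counts_0", "counts_1"]].to_numpy(dtype=float)
    fused["n_counts"] = np.sum(~np.isnan(cnt), axis=1)
    fused["counts_30s"] = np.nansum(cnt, axis=1)
    for j in (0, 1):
        col = cnt[:, j]
        codes = np.full(len(fused), -1, dtype=np.int8)
        ok = ~np.isnan(col)
        if ok.any():
            codes[ok] = classify_intensity(col[ok].astype(np.int64))
        fused[f"intensity_{j}"] = codes
    return fused


def add_movement(fused: pd.DataFrame, valid: np.ndarray | None = None) -> pd.DataFrame:
    """Attach valid_fix, speed_kmh and movement columns to fused epochs.

    Speed chains over valid located fixes only, using the actual elapsed
    time.  Epochs with undefined speed (first fix of a chain, dropout,
    invalid fix) default to stationary, which avoids phantom trips.
    """
    out = fused.copy()
    has_fix = out["has_fix"].to_numpy(dtype=bool)
    located = out.loc[has_fix]
    if valid is None:
        valid_loc = flag_invalid_fixes(located) if len(located) else np.array([], bool)
    else:
        valid_loc = np.asarray(valid, dtype=bool)
    valid_col = np.zeros(len(out), dtype=bool)
    valid_col[np.flatnonzero(has_fix)] = valid_loc
    out["valid_fix"] = valid_col

    speed = np.full(len(out), np.nan)
    idx = np.flatnonzero(valid_col)
    if len(idx) > 1:
        lat = out["lat"].to_numpy(dtype=float)[idx]
        lon = out["lon"].to_numpy(dtype=float)[idx]
        ts = out["timestamp"].to_numpy()[idx]
        dist = haversine_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])
        dt = (ts[1:] - ts[:-1]) / np.timedelta64(1, "s")
        speed[idx[1:]] = compute_speed(dist, dt)
    out["speed_kmh"] = speed
    movement = np.full(len(out), STATIONARY, dtype=object)
    defined = ~np.isnan(speed)
    movement[defined] = classify_movement(speed[defined])
    movement[~valid_col] = STATIONARY
    out["movement"] = movement
    return out


def smooth_movement(states, smooth_epochs: int = 1):
    """Absorb movement-state flickers of up to ``smooth_epochs`` epochs
    flanked by one identical state on both sides into that state."""
    s = list(states)
    if smooth_epochs <= 0 or len(s) < 3:
        return np.asarray(s, dtype=object)
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, len(s) + 1):
            if i == len(s) or s[i] != s[start]:
                runs.append((start, i))
                start = i
        for k in range(1, len(runs) - 1):
            a, b = runs[k]
            if b - a <= smooth_epochs:
                left = s[runs[k - 1][0]]
                right = s[runs[k + 1][0]]
                if left == right and left != s[a]:
                    for j in range(a, b):
                        s[j] = left
                    changed = True
                    break
    return np.asarray(s, dtype=object)


def apply_corrections(fused: pd.DataFrame, corrections: pd.DataFrame | None) -> pd.DataFrame:
    """Overwrite movement (or POS label) inside declared windows.

    ``corrections`` columns: participant_id (optional when fused is one
    participant), start, end, column, value.  Rows apply in order, so a
    later overlapping row wins; windows matching no epoch warn.
    """
    out = fused.copy()
    if corrections is None or len(corrections) == 0:
        return out
    seen = np.zeros(len(out), dtype=bool)
    for _, row in corrections.iterrows():
        mask = (out["timestamp"] >= row["start"]) & (out["timestamp"] < row["end"])
        if "participant_id" in corrections.columns and "participant_id" in out.columns:
            mask &= out["participant_id"] == row["participant_id"]
        if not mask.any():
            warnings.warn(f"correction window {row['start']}..{row['end']} matches no epochs")
            continue
        if (seen & mask.to_numpy()).any():
            warnings.warn("overlapping correction windows: later row wins")
        seen |= mask.to_numpy()
        col = row.get("column", "movement")
        out.loc[mask, col] = row["value"]
    return out
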