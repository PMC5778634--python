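"""Spatial fusion: distance, speed bands, plausibility flags, alignment."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from posuse.fusion import (
    EARTH_RADIUS_M,
    align_streams,
    apply_corrections,
    classify_movement,
    compute_speed,
    flag_invalid_fixes,
    haversine_distance,
    smooth_movement,
)


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_distance(51.05, 3.72, 51.05, 3.72) == 0.0

    def test_meridian_arc(self):
        # 0.01 deg of latitude = R * 0.01 * pi/180
        expected = EARTH_RADIUS_M * math.radians(0.01)
        assert haversine_distance(0.0, 0.0, 0.01, 0.0) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1111.95, abs=0.01)

    def test_agrees_with_independent_geodesic_routine(self):
        from sklearn.metrics.pairwise import haversine_distances

        rng = np.random.default_rng(3)
        lat = rng.uniform(-80, 80, 20)
        lon = rng.uniform(-179, 179, 20)
        ours = haversine_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])
        pts = np.radians(np.column_stack([lat, lon]))
        theirs = np.array(
            [
                haversine_distances(pts[i : i + 1], pts[i + 1 : i + 2])[0, 0]
                for i in range(19)
            ]
        ) * EARTH_RADIUS_M
        np.testing.assert_allclose(ours, theirs, rtol=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-80, 80, 50), rng.uniform(-179, 179, 50)
        b = rng.uniform(-80, 80, 50), rng.uniform(-179, 179, 50)
        np.testing.assert_allclose(
            haversine_distance(a[0], a[1], b[0], b[1]),
            haversine_distance(b[0], b[1], a[0], a[1]),
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_distance(91.0, 0.0, 0.0, 0.0)


class TestSpeed:
    def test_arithmetic(self):
        assert compute_speed(250.0 / 3.0, 30.0) == pytest.approx(10.0)
        assert compute_speed(0.0, 30.0) == 0.0
        assert compute_speed(250.0, 60.0) == pytest.approx(15.0)

    def test_zero_elapsed_rejected(self):
        with pytest.raises(ValueError):
            compute_speed(10.0, 0.0)


@pytest.mark.parametrize(
    "speed,state",
    [
        (0.0, "stationary"),
        (0.99, "stationary"),
        (1.0, "pedestrian"),
        (9.99, "pedestrian"),
        (10.0, "bicycle"),
        (24.99, "bicycle"),
        (25.0, "motorized"),
        (130.0, "motorized"),
    ],
)
def test_speed_band_boundaries(speed, state):
    assert classify_movement(speed) == state


def test_speed_bands_partition():
    rng = np.random.default_rng(0)
    states = classify_movement(rng.uniform(0, 200, 500))
    assert set(states) <= {"stationary", "pedestrian", "bicycle", "motorized"}


def _track(rows):
    ts = pd.date_range("2015-10-05T10:00:00", periods=len(rows), freq="30s")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "lat": [r[0] for r in rows],
            "lon": [r[1] for r in rows],
            "elevation_m": [r[2] for r in rows],
        }
    )


DEG_PER_M_LAT = 1.0 / (EARTH_RADIUS_M * math.pi / 180.0)


class TestInvalidFixes:
    def test_distance_and_speed_violation(self):
        # 1100 m in 30 s = 132 km/h: invalid by both rules
        track = _track([(51.0, 3.7, 10.0), (51.0 + 1100 * DEG_PER_M_LAT, 3.7, 10.0)])
        assert list(flag_invalid_fixes(track)) == [True, False]

    def test_900_m_jump_valid(self):
        track = _track([(51.0, 3.7, 10.0), (51.0 + 900 * DEG_PER_M_LAT, 3.7, 10.0)])
        assert list(flag_invalid_fixes(track)) == [True, True]

    def test_elevation_violation(self):
        track = _track([(51.0, 3.7, 10.0), (51.0 + 10 * DEG_PER_M_LAT, 3.7, 111.1)])
        assert list(flag_invalid_fixes(track)) == [True, False]

    def test_missing_elevation_skips_elevation_rule(self):
        track = _track([(51.0, 3.7, np.nan), (51.0 + 10 * DEG_PER_M_LAT, 3.7, 500.0)])
        assert list(flag_invalid_fixes(track)) == [True, True]

    def test_chain_restarts_from_last_valid(self):
        jump = 1200 * DEG_PER_M_LAT
        track = _track(
            [(51.0, 3.7, 10.0), (51.0 + jump, 3.7, 10.0), (51.0, 3.7, 10.0)]
        )
        # second fix jumps 1.2 km (invalid); third is back at the first
        assert list(flag_invalid_fixes(track)) == [True, False, True]

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n = 30
            lat = 51.0 + np.cumsum(rng.choice([0, 200, 600, 1200], n) * DEG_PER_M_LAT)
            lon = np.full(n, 3.7)
            elev = rng.choice([10.0, 50.0, 160.0, np.nan], n)
            track = _track(list(zip(lat, lon, elev)))
            got = list(flag_invalid_fixes(track))
            assert got == brute_force_flags(track)


def brute_force_flags(track):
    """Literal triple-threshold evaluation with chain restart."""
    lat = track["lat"].to_list()
    lon = track["lon"].to_list()
    elev = track["elevation_m"].to_list()
    ts = track["timestamp"].to_list()
    flags = [True]
    last = 0
    for i in range(1, len(lat)):
        phi1, phi2 = math.radians(lat[last]), math.radians(lat[i])
        dphi = phi2 - phi1
        dlam = math.radians(lon[i] - lon[last])
        a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
        dist = 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))
        dt = (ts[i] - ts[last]).total_seconds()
        bad = dist / dt * 3.6 > 130.0 or dist > 1000.0
        if not (math.isnan(elev[i]) or math.isnan(elev[last])):
            bad = bad or abs(elev[i] - elev[last]) > 100.0
        flags.append(not bad)
        if not bad:
            last = i
    return flags


class TestAlign:
    def _streams(self, n_fix=4, drop_fix=(), drop_count=()):
        ts = pd.date_range("2015-10-05T10:00:00", periods=n_fix, freq="30s")
        gps = pd.DataFrame(
            {"timestamp": ts, "lat": 51.0, "lon": 3.7, "elevation_m": 10.0}
        ).drop(index=list(drop_fix)).reset_index(drop=True)
        cts = pd.date_range("2015-10-05T10:00:00", periods=2 * n_fix, freq="15s")
        counts = pd.DataFrame({"timestamp": cts, "counts": 100}).drop(
            index=list(drop_count)
        ).reset_index(drop=True)
        return gps, counts

    def test_pairs_two_counts_per_fix(self):
        gps, counts = self._streams()
        fused = align_streams(gps, counts)
        assert len(fused) == 4
        assert (fused["n_counts"] == 2).all()
        assert (fused["counts_30s"] == 200).all()

    def test_partial_epoch_on_count_dropout(self):
        gps, counts = self._streams(drop_count=(1,))
        fused = align_streams(gps, counts)
        assert fused["n_counts"].to_list() == [1, 2, 2, 2]
        assert fused["counts_30s"].iloc[0] == 100

    def test_counts_during_gps_dropout_become_location_missing(self):
        gps, counts = self._streams(drop_fix=(2,))
        fused = align_streams(gps, counts)
        assert len(fused) == 4  # slot retained, anchored on the count grid
        missing = fused.loc[~fused["has_fix"]]
        assert len(missing) == 1
        assert missing["n_counts"].iloc[0] == 2
        assert np.isnan(missing["lat"].iloc[0])


def test_smoothing_absorbs_single_flicker():
    states = ["stationary"] * 3 + ["pedestrian"] + ["stationary"] * 3
    out = smooth_movement(states, 1)
    assert list(out) == ["stationary"] * 7


def test_smoothing_keeps_real_transitions():
    states = ["stationary"] * 3 + ["pedestrian"] * 5 + ["bicycle"] * 4
    assert list(smooth_movement(states, 1)) == states


class TestCorrections:
    def _fused(self):
        ts = pd.date_range("2015-10-05T10:00:00", periods=6, freq="30s")
        return pd.DataFrame(
            {"timestamp": ts, "movement": ["bicycle"] * 6, "participant_id": "P1"}
        )

    def test_window_overrides_movement(self):
        corr = pd.DataFrame(
            [
                {
                    "participant_id": "P1",
                    "start": pd.Timestamp("2015-10-05T10:00:30"),
                    "end": pd.Timestamp("2015-10-05T10:02:00"),
                    "column": "movement",
                    "value": "motorized",
                }
            ]
        )
        out = apply_corrections(self._fused(), corr)
        assert out["movement"].to_list() == [
            "bicycle", "motorized", "motorized", "motorized", "bicycle", "bicycle",
        ]

    def test_empty_table_is_identity(self):
        fused = self._fused()
        out = apply_corrections(fused, pd.DataFrame())
        pd.testing.assert_frame_equal(out, fused)

    def test_overlapping_later_row_wins(self):
        base = {
            "participant_id": "P1",
            "start": pd.Timestamp("2015-10-05T10:00:00"),
            "end": pd.Timestamp("2015-10-05T10:03:00"),
            "column": "movement",
        }
        corr = pd.DataFrame([{**base, "value": "motorized"}, {**base, "value": "pedestrian"}])
        with pytest.warns(UserWarning):
            out = apply_corrections(self._fused(), corr)
        assert set(out["movement"].iloc[:6]) == {"pedestrian"}

    def test_unmatched_window_warns(self):
        corr = pd.DataFrame(
            [
                {
                    "participant_id": "P1",
                    "start": pd.Timestamp("2016-01-01"),
                    "end": pd.Timestamp("2016-01-02"),
                    "column": "movement",
                    "value": "motorized",
                }
            ]
        )
        with pytest.warns(UserWarning):
            apply_corrections(self._fused(), corr)
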