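"""Domain assignment, consolidation and the annotation join."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from posuse.domains import (
    BUFFER_M,
    Segment,
    assign_domains,
    consolidate,
    join_annotations,
    UNKNOWN_POS,
)
from posuse.fusion import EARTH_RADIUS_M
from posuse.io_formats import ClassTimetable, DayTimetable

DEG_PER_M = 1.0 / (EARTH_RADIUS_M * math.pi / 180.0)

HOME = (51.00, 3.70)
SCHOOL = (51.02, 3.72)


def _timetable():
    tt = ClassTimetable("S1", "S1_C1")
    for wd in range(5):
        tt.weekdays[wd] = DayTimetable(
            (dt.time(8, 30), dt.time(16, 0)),
            [(dt.time(14, 0), dt.time(15, 0))] if wd == 0 else [],
            [(dt.time(10, 10), dt.time(10, 25))],
        )
    return tt


def _epoch(ts, lat, lon, movement="stationary"):
    return {
        "participant_id": "P1",
        "timestamp": pd.Timestamp(ts),
        "lat": lat,
        "lon": lon,
        "movement": movement,
        "worn": True,
        "located": True,
        "intensity_0": 0,
        "intensity_1": 1,
    }


def _assign(rows):
    return assign_domains(
        pd.DataFrame(rows), HOME[0], HOME[1], SCHOOL[0], SCHOOL[1], _timetable()
    )


class TestAssign:
    def test_school_class_inside_hours(self):
        # Monday 2015-10-05, 10:00, 50 m from the school point
        row = _epoch("2015-10-05T10:00:00", SCHOOL[0] + 50 * DEG_PER_M, SCHOOL[1])
        assert _assign([row])["domain"].iloc[0] == "school_class"

    def test_same_location_outside_hours_is_leisure(self):
        row = _epoch("2015-10-05T20:00:00", SCHOOL[0] + 50 * DEG_PER_M, SCHOOL[1])
        assert _assign([row])["domain"].iloc[0] == "leisure"

    def test_recess_and_pe_blocks(self):
        recess = _epoch("2015-10-05T10:15:00", SCHOOL[0], SCHOOL[1])
        pe = _epoch("2015-10-05T14:30:00", SCHOOL[0], SCHOOL[1])
        cls = _epoch("2015-10-05T11:00:00", SCHOOL[0], SCHOOL[1])
        out = _assign([recess, cls, pe])
        assert out["domain"].to_list() == ["school_recess", "school_class", "school_pe"]

    def test_school_weekend_is_leisure(self):
        row = _epoch("2015-10-03T10:00:00", SCHOOL[0], SCHOOL[1])  # Saturday
        assert _assign([row])["domain"].iloc[0] == "leisure"

    @pytest.mark.parametrize(
        "offset_m,expected", [(99.9, "home"), (100.1, "leisure")]
    )
    def test_home_buffer_boundary_inclusive(self, offset_m, expected):
        row = _epoch("2015-10-05T19:00:00", HOME[0] + offset_m * DEG_PER_M, HOME[1])
        assert _assign([row])["domain"].iloc[0] == expected

    def test_transport_keeps_mode(self):
        row = _epoch("2015-10-05T17:00:00", HOME[0], HOME[1], movement="bicycle")
        assert _assign([row])["domain"].iloc[0] == "transport:bicycle"

    def test_missing_home_rejected(self):
        with pytest.raises(ValueError):
            assign_domains(
                pd.DataFrame([_epoch("2015-10-05T10:00:00", 51.0, 3.7)]),
                np.nan, np.nan, SCHOOL[0], SCHOOL[1], _timetable(),
            )

    def test_assignment_is_order_independent(self):
        rows = [
            _epoch("2015-10-05T10:00:00", SCHOOL[0], SCHOOL[1]),
            _epoch("2015-10-05T19:00:00", HOME[0], HOME[1]),
            _epoch("2015-10-05T20:00:00", 51.05, 3.75),
        ]
        fwd = _assign(rows)["domain"].to_list()
        rev = _assign(rows[::-1])["domain"].to_list()
        assert fwd == rev[::-1]


def _labelled(labels, start="2015-10-05T17:00:00"):
    ts = pd.date_range(start, periods=len(labels), freq="30s")
    return pd.DataFrame(
        {
            "participant_id": "P1",
            "timestamp": ts,
            "domain": labels,
            "lat": 51.0,
            "lon": 3.7,
            "intensity_0": 0,
            "intensity_1": 0,
        }
    )


class TestConsolidate:
    def test_run_length_encoding(self):
        segs = consolidate(_labelled(["home"] * 3 + ["leisure"] * 2 + ["home"]))
        assert [(s.label, s.duration_min) for s in segs] == [
            ("home", 1.5), ("leisure", 1.0), ("home", 0.5),
        ]

    def test_mode_change_splits_trips(self):
        labels = ["transport:pedestrian"] * 4 + ["transport:bicycle"] * 4
        segs = consolidate(_labelled(labels))
        assert [(s.kind, s.label) for s in segs] == [
            ("trip", "pedestrian"), ("trip", "bicycle"),
        ]

    def test_location_missing_breaks_runs(self):
        segs = consolidate(_labelled(["home"] * 3 + [None] * 2 + ["home"] * 3))
        assert [s.duration_min for s in segs] == [1.5, 1.5]

    def test_partition_of_labelled_time(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["home", "leisure", "transport:pedestrian", None], 400).tolist()
        segs = consolidate(_labelled(labels))
        labelled_min = 0.5 * sum(1 for l in labels if l is not None)
        assert sum(s.duration_min for s in segs) == pytest.approx(labelled_min)

    def test_intensity_minutes_accumulate(self):
        df = _labelled(["leisure"] * 4)
        df["intensity_0"] = [0, 1, 2, 3]
        df["intensity_1"] = [0, 1, 2, 3]
        (seg,) = consolidate(df)
        assert seg.intensity_min == {"st": 0.5, "lpa": 0.5, "mpa": 0.5, "vpa": 0.5}
        assert sum(seg.intensity_min.values()) == pytest.approx(seg.duration_min)


def _event(start, end, label="leisure", kind="event"):
    return Segment(
        participant_id="P1",
        date=dt.date(2015, 10, 5),
        start=pd.Timestamp(start),
        end=pd.Timestamp(end),
        kind=kind,
        label=label,
        duration_min=(pd.Timestamp(end) - pd.Timestamp(start)).total_seconds() / 60,
    )


def _ann(start, end, category="park", pid="P1"):
    return {
        "participant_id": pid,
        "start": pd.Timestamp(start),
        "end": pd.Timestamp(end),
        "pos_category": category,
        "company": ("friends/classmates",),
        "reasons": ("habit",),
        "activities": ("walking",),
    }


class TestJoinAnnotations:
    def test_window_inside_event(self):
        ev = _event("2015-10-05T15:00:00", "2015-10-05T15:40:00")
        join_annotations([ev], pd.DataFrame([_ann("2015-10-05T15:05:00", "2015-10-05T15:35:00")]))
        assert ev.pos_category == "park"
        assert ev.company == ("friends/classmates",)

    def test_zero_overlap_warns_and_unused(self):
        ev = _event("2015-10-05T15:00:00", "2015-10-05T15:40:00")
        with pytest.warns(UserWarning):
            join_annotations([ev], pd.DataFrame([_ann("2015-10-05T18:00:00", "2015-10-05T18:30:00")]))
        assert ev.pos_category == UNKNOWN_POS

    def test_unannotated_leisure_gets_unknown(self):
        ev = _event("2015-10-05T15:00:00", "2015-10-05T15:40:00")
        join_annotations([ev], pd.DataFrame())
        assert ev.pos_category == UNKNOWN_POS

    def test_maximal_overlap_matches_enumeration(self):
        """Greedy max-overlap assignment equals the brute-force optimum on
        every pairing of two events with one annotation each."""
        e1 = _event("2015-10-05T15:00:00", "2015-10-05T15:30:00")
        e2 = _event("2015-10-05T16:00:00", "2015-10-05T16:30:00")
        anns = pd.DataFrame(
            [
                _ann("2015-10-05T15:10:00", "2015-10-05T15:40:00", "park"),
                _ann("2015-10-05T15:50:00", "2015-10-05T16:20:00", "square"),
            ]
        )

        def overlap(ev, ann):
            return max(
                0.0,
                (min(ev.end, ann["end"]) - max(ev.start, ann["start"])).total_seconds(),
            )

        # brute force: each annotation independently to its best event
        best = {}
        for _, ann in anns.iterrows():
            ovs = [overlap(e, ann) for e in (e1, e2)]
            best[ann["pos_category"]] = int(np.argmax(ovs))
        join_annotations([e1, e2], anns)
        assert best == {"park": 0, "square": 1}
        assert (e1.pos_category, e2.pos_category) == ("park", "square")

    def test_tie_goes_to_earlier_event(self):
        e1 = _event("2015-10-05T15:00:00", "2015-10-05T15:30:00")
        e2 = _event("2015-10-05T16:00:00", "2015-10-05T16:30:00")
        # 10 min overlap with each event
        ann = _ann("2015-10-05T15:20:00", "2015-10-05T16:10:00")
        join_annotations([e1, e2], pd.DataFrame([ann]))
        assert e1.pos_category == "park"
        assert e2.pos_category == UNKNOWN_POS
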