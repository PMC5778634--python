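"""POS-visit extraction, trip attribution and participant aggregation.

Only leisure events carrying one of the nine public-open-space (POS)
categories count as visits; time in POS includes the trips to and from
the POS.  Concretely: the trip whose end abuts the event start (within
one 30 s epoch) is attributed as the inbound trip, the trip whose start
abuts the event end as the outbound trip.  A trip bridging two POS
events is attributed exactly once, as the outbound trip of the earlier
visit.  Trips whose adjacent events are home, school or unannotated
leisure are never attributed, however much POS territory they traverse:
cycling through a park on the way to school contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accel import INTENSITY_LABELS
from .domains import LEISURE, UNKNOWN_POS, Segment

__all__ = ["POS_CATEGORIES", "COMPANY_CATEGORIES", "PosVisit",
           "extract_pos_visits", "summarize_participant", "cohort_descriptives"]

POS_CATEGORIES = (
    "street",
    "shopping street/mall",
    "square",
    "park",
    "outdoor sports ground/playground",
    "parking lot",
    "vacant lot",
    "public transportation stop/station",
)

COMPANY_CATEGORIES = (
    "friends/classmates",
    "siblings/cousins",
    "parents/grandparents",
    "alone",
    "organisation",
)

#: adjacency tolerance between a trip boundary and an event boundary
ADJACENCY_S = 30.0


@dataclass
class PosVisit:
    participant_id: str
    date: object
    event: Segment
    inbound: Segment | None = None
    outbound: Segment | None = None

    @property
    def pos_category(self) -> str:
        return self.event.pos_category

    @property
    def company(self) -> tuple:
        return self.event.company

    def _parts(self):
        return [s for s in (self.inbound, self.event, self.outbound) if s is not None]

    @property
    def total_min(self) -> float:
        return sum(s.duration_min for s in self._parts())

    def intensity_min(self) -> dict[str, float]:
        out = {k: 0.0 for k in INTENSITY_LABELS}
        for s in self._parts():
            for k in INTENSITY_LABELS:
                out[k] += s.intensity_min.get(k, 0.0)
        return out


def _is_pos_event(seg: Segment) -> bool:
    return (
        seg.kind == "event"
        and seg.label == LEISURE
        and seg.pos_category is not None
        and seg.pos_category != UNKNOWN_POS
    )


def extract_pos_visits(segments: list[Segment]) -> list[PosVisit]:
    """Extract POS visits with attributed trips from one day's ordered
    segments."""
    segs = sorted(segments, key=lambda s: s.start)
    used: set[int] = set()
    visits: list[PosVisit] = []
    for i, seg in enumerate(segs):
        if not _is_pos_event(seg):
            continue
        visit = PosVisit(seg.participant_id, seg.date, seg)
        if i > 0:
            prev = segs[i - 1]
            gap = (seg.start - prev.end).total_seconds()
            if prev.kind == "trip" and 0 <= gap <= ADJACENCY_S and id(prev) not in used:
                visit.inbound = prev
                used.add(id(prev))
        if i + 1 < len(segs):
            nxt = segs[i + 1]
            gap = (nxt.start - seg.end).total_seconds()
            if nxt.kind == "trip" and 0 <= gap <= ADJACENCY_S and id(nxt) not in used:
                visit.outbound = nxt
                used.add(id(nxt))
        visits.append(visit)
    return visits


def summarize_participant(
    participant: pd.Series,
    day_tables: list[dict],
    weather: pd.DataFrame | None = None,
) -> dict:
    """Collapse a participant's valid days into one analysis row.

    ``day_tables`` holds one dict per *valid* day with keys ``date``,
    ``wear_min``, ``intensity_min`` (worn-day totals per class),
    ``visits`` (list of :class:`PosVisit`) and ``segments``.  Per-day
    means divide by the number of valid days.  POS intensity minutes
    include attributed trip minutes.  Company counts increment once per
    visit per reported company category.
    """
    n_days = len(day_tables)
    if n_days == 0:
        raise ValueError("participant reached aggregation with zero valid days")
    total = {k: 0.0 for k in INTENSITY_LABELS}
    pos = {k: 0.0 for k in INTENSITY_LABELS}
    wear = 0.0
    pos_min = 0.0
    n_visits = 0
    company_counts = {c: 0 for c in COMPANY_CATEGORIES}
    for day in day_tables:
        wear += day["wear_min"]
        for k in INTENSITY_LABELS:
            total[k] += day["intensity_min"].get(k, 0.0)
        for v in day["visits"]:
            n_visits += 1
            pos_min += v.total_min
            vi = v.intensity_min()
            for k in INTENSITY_LABELS:
                pos[k] += vi[k]
            for c in v.company:
                if c in company_counts:
                    company_counts[c] += 1
    row = {
        "participant_id": participant["participant_id"],
        "school_id": participant["school_id"],
        "n_days": n_days,
        "wear_min_day": wear / n_days,
        "pos_visits_day": n_visits / n_days,
        "used_pos": n_visits > 0,
        "pos_min_day": pos_min / n_days,
    }
    for k in INTENSITY_LABELS:
        row[f"total_{k}_day"] = total[k] / n_days
        row[f"pos_{k}_day"] = pos[k] / n_days
    row["total_mvpa_day"] = row["total_mpa_day"] + row["total_vpa_day"]
    row["pos_mvpa_day"] = row["pos_mpa_day"] + row["pos_vpa_day"]
    for c in COMPANY_CATEGORIES:
        key = c.split("/")[0]
        row[f"visits_{key}_day"] = company_counts[c] / n_days
    for col in ("age", "gender", "ethnicity", "education", "ses", "sport_club", "residence"):
        if col in participant:
            row[col] = participant[col]
    if weather is not None and len(weather):
        dates = [day["date"] for day in day_tables]
        wsel = weather[weather["date"].isin(dates)]
        if len(wsel):
            row["rain_mm"] = float(wsel["rain_mm"].mean())
            row["sun_min"] = float(wsel["sun_min"].mean())
            row["temp_c"] = float(wsel["temp_c"].mean())
    return row


def _multi_response_pct(visits: list[PosVisit], getter) -> dict[str, float]:
    n = len(visits)
    tally: dict[str, int] = {}
    for v in visits:
        for item in getter(v):
            tally[item] = tally.get(item, 0) + 1
    return {k: 100.0 * c / n for k, c in sorted(tally.items(), key=lambda kv: -kv[1])}


def cohort_descriptives(summaries: pd.DataFrame, visits: list[PosVisit]) -> dict:
    """Descriptive report: % POS users, visit frequency among users, and
    the visit mix by company (multi-response), POS category
    (single-response, sums to 100 up to rounding), reason and activity."""
    if summaries.empty:
        raise ValueError("empty cohort")
    users = summaries["used_pos"]
    report = {
        "n_participants": int(len(summaries)),
        "n_visits": int(len(visits)),
        "pct_pos_users": 100.0 * float(users.mean()),
        "mean_visits_day_users": (
            float(summaries.loc[users, "pos_visits_day"].mean()) if users.any() else 0.0
        ),
    }
    if visits:
        n = len(visits)
        cat = {}
        for v in visits:
            cat[v.pos_category] = cat.get(v.pos_category, 0) + 1
        report["pct_visits_by_category"] = {
            k: 100.0 * c / n for k, c in sorted(cat.items(), key=lambda kv: -kv[1])
        }
        report["pct_visits_by_company"] = _multi_response_pct(visits, lambda v: v.company)
        report["pct_visits_by_reason"] = _multi_response_pct(visits, lambda v: v.event.reasons)
        report["pct_visits_by_activity"] = _multi_response_pct(
            visits, lambda v: v.event.activities
        )
    for col in ("pos_min_day", "pos_mvpa_day", "total_mvpa_day"):
        q = summaries[col].quantile([0.25, 0.5, 0.75])
        report[f"{col}_median_q1_q3"] = [float(q[0.5]), float(q[0.25]), float(q[0.75])]
    return report
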