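"""Synthetic cohort generator with ground truth.

Simulates a school-recruited adolescent cohort wearing a hip GPS device
(one fix per 30 s) and an accelerometer (one count per 15 s) over a few
days, together with the interview-derived POS annotations, school
timetables and daily weather — the six input streams the pipeline
consumes — plus a ground-truth record of every generated segment, so
every downstream stage has a known-answer test surface.

Design choices (documented in the methods note): days are built from
anchor locations (home, school, POS sites) joined by constant-speed
great-circle trips snapped to the 30 s grid; counts come from
context-conditional lognormal mixtures whose class medians sit inside
the target intensity band, so labels are recoverable; weekends differ
from weekdays only by the absence of the school block; one master seed
is split per participant with counter-based seed sequences, making the
dataset reproducible independent of generation order.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .accel import classify_intensity
from .fusion import haversine_distance
from .io_formats import (
    ClassTimetable,
    DayTimetable,
    write_annotations,
    write_cohort,
    write_count_log,
    write_gps_log,
    write_schools,
    write_timetables,
    write_weather,
)
from .visits import COMPANY_CATEGORIES, POS_CATEGORIES

__all__ = [
    "BehaviourConfig",
    "EffectsConfig",
    "SimulationConfig",
    "generate_cohort",
    "generate_day",
    "generate_dataset",
    "write_dataset",
    "GROUND_TRUTH_PREFIX",
]

EPOCH_S = 30
DEG_LAT_M = 111_195.0  # metres per degree of latitude on the reference sphere

#: files carrying ground truth start with this prefix; the pipeline CLI
#: refuses to read them, so the oracle can never leak into the analysis.
GROUND_TRUTH_PREFIX = "ground_truth"


# ---------------------------------------------------------------------------
# configuration

@dataclass
class BehaviourConfig:
    """Behavioural parameters of the simulated days.

    Speeds must respect the transport bands (stationary < pedestrian <
    bicycle < motorized); dwell times are gamma distributed in minutes.
    """

    mode_speed_kmh: dict = field(
        default_factory=lambda: {"pedestrian": 5.0, "bicycle": 16.0, "motorized": 35.0}
    )
    pos_visit_prob: float = 0.5        # baseline per-day probability of visiting a POS
    extra_visit_prob: float = 0.4      # two extra-visit coin flips -> mean 1.8 visits/visit day
    dwell_mean_min: float = 20.0
    dwell_shape: float = 2.0
    other_leisure_prob: float = 0.15   # unannotated (non-POS) leisure outing
    nonwear_prob: float = 0.15         # per-day probability of an evening non-wear bout
    nonwear_min_range: tuple = (60.0, 120.0)
    short_day_prob: float = 0.08       # device taken off early -> invalid day
    gps_dropout_prob: float = 0.005    # per-fix missingness
    jitter_m: float = 1.5              # GPS positional noise (sd per axis)
    wear_start: str = "07:30"
    wear_end: str = "22:00"
    pos_category_probs: dict = field(
        default_factory=lambda: {
            "public transportation stop/station": 0.710,
            "street": 0.094,
            "parking lot": 0.054,
            "square": 0.035,
            "shopping street/mall": 0.045,
            "outdoor sports ground/playground": 0.029,
            "park": 0.029,
            "vacant lot": 0.004,
        }
    )
    company_probs: dict = field(
        default_factory=lambda: {
            "friends/classmates": 0.598,
            "siblings/cousins": 0.164,
            "parents/grandparents": 0.164,
            "alone": 0.156,
            "organisation": 0.025,
        }
    )
    reasons: tuple = (
        "wait for something/someone",
        "friends/siblings wanted to go",
        "other",
        "close to home/school",
        "passing by and stayed",
        "habit",
    )
    reason_probs: tuple = (0.303, 0.174, 0.174, 0.138, 0.101, 0.110)
    activities: tuple = ("standing", "walking", "sitting/lying down", "ball sports", "biking")
    activity_probs: tuple = (0.431, 0.385, 0.138, 0.064, 0.028)
    #: intensity-class mixture per movement/location context
    count_context_probs: dict = field(
        default_factory=lambda: {
            "home": (0.65, 0.30, 0.04, 0.01),
            "school_class": (0.80, 0.18, 0.02, 0.00),
            "school_recess": (0.30, 0.45, 0.20, 0.05),
            "school_pe": (0.10, 0.30, 0.40, 0.20),
            "trip_pedestrian": (0.05, 0.45, 0.45, 0.05),
            "trip_bicycle": (0.10, 0.40, 0.40, 0.10),
            "trip_motorized": (0.85, 0.14, 0.01, 0.00),
            "pos": (0.35, 0.45, 0.15, 0.05),
            "pos_sports": (0.15, 0.35, 0.30, 0.20),
            "leisure_other": (0.60, 0.30, 0.08, 0.02),
        }
    )


@dataclass
class EffectsConfig:
    """True coefficients linking demographics to POS use.

    ``occurrence`` acts on the log-odds of a POS-visit day, ``amount``
    on log dwell minutes; keys are derived covariates (girl,
    non_western, age_c = age - 14, sport_club, low_ses).
    """

    occurrence: dict = field(default_factory=lambda: {"non_western": 0.8, "girl": -0.4})
    amount: dict = field(default_factory=lambda: {"girl": -0.3})


@dataclass
class SimulationConfig:
    n_participants: int = 173
    n_schools: int = 6
    n_days: int = 2
    start_date: str = "2015-10-02"      # a Friday in the study season: one week + one weekend day
    #: (lat_min, lat_max, lon_min, lon_max), WGS84 decimal degrees
    study_area: tuple = (51.00, 51.10, 3.65, 3.80)
    sites_per_category: int = 4
    behaviour: BehaviourConfig = field(default_factory=BehaviourConfig)
    effects: EffectsConfig = field(default_factory=EffectsConfig)
    school_sigma: float = 0.3
    #: marginal demographics of the cohort
    girl_prob: float = 0.544
    age_mean: float = 14.2
    age_sd: float = 1.1
    non_western_prob: float = 0.283
    education_probs: dict = field(
        default_factory=lambda: {"general": 0.688, "vocational": 0.220, "technical": 0.092}
    )
    low_ses_prob: float = 0.225
    sport_club_prob: float = 0.580
    residence_probs: dict = field(
        default_factory=lambda: {"rural": 0.069, "suburban": 0.168, "urban": 0.763}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0 or self.n_schools <= 0 or self.n_days <= 0:
            raise ValueError("n_participants, n_schools and n_days must be positive")
        b = self.behaviour
        probs = [
            b.pos_visit_prob, b.extra_visit_prob, b.other_leisure_prob,
            b.nonwear_prob, b.gps_dropout_prob, self.girl_prob,
            self.non_western_prob, self.low_ses_prob, self.sport_club_prob,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        s = b.mode_speed_kmh
        if not (1.0 <= s["pedestrian"] < 10.0 <= s["bicycle"] < 25.0 <= s["motorized"]):
            raise ValueError("mode speeds must respect the transport bands")
        if b.dwell_mean_min <= 0 or b.dwell_shape <= 0:
            raise ValueError("dwell times must be strictly positive")

    def noise_free(self) -> "SimulationConfig":
        """A copy with no non-wear, no short days, no GPS dropout and no
        positional noise."""
        b = replace(
            self.behaviour,
            nonwear_prob=0.0,
            gps_dropout_prob=0.0,
            jitter_m=0.0,
            short_day_prob=0.0,
        )
        return replace(self, behaviour=b)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        beh = BehaviourConfig(**raw.pop("behaviour", {}))
        eff = EffectsConfig(**raw.pop("effects", {}))
        return cls(behaviour=beh, effects=eff, **raw)


# ---------------------------------------------------------------------------
# helpers

#: class-conditional lognormal count parameters (log-median, sigma) per 15 s;
#: sedentary draws are zero-inflated so genuine zero epochs occur.
_CLASS_COUNTS = {
    0: (math.log(25.0), 0.9),
    1: (math.log(600.0), 0.55),
    2: (math.log(3000.0), 0.18),
    3: (math.log(6000.0), 0.35),
}
_ZERO_INFLATION_ST = 0.35


def _draw_counts(context: str, n: int, cfg: BehaviourConfig, rng) -> np.ndarray:
    probs = np.asarray(cfg.count_context_probs[context], dtype=float)
    probs = probs / probs.sum()
    classes = rng.choice(4, size=n, p=probs)
    out = np.empty(n, dtype=np.int64)
    for c in range(4):
        idx = np.flatnonzero(classes == c)
        if len(idx) == 0:
            continue
        mu, sigma = _CLASS_COUNTS[c]
        vals = np.rint(rng.lognormal(mu, sigma, size=len(idx))).astype(np.int64)
        if c == 0:
            vals[rng.random(len(idx)) < _ZERO_INFLATION_ST] = 0
        out[idx] = vals
    return out


def _offset_point(lat: float, lon: float, dist_m: float, bearing_rad: float):
    dlat = dist_m * math.cos(bearing_rad) / DEG_LAT_M
    dlon = dist_m * math.sin(bearing_rad) / (DEG_LAT_M * math.cos(math.radians(lat)))
    return lat + dlat, lon + dlon


def effect_covariates(participant) -> dict[str, float]:
    """Derived 0/1 (and centred-age) covariates the true effects act on."""
    return {
        "girl": 1.0 if participant["gender"] == "female" else 0.0,
        "non_western": 1.0 if participant["ethnicity"] == "non-western-European" else 0.0,
        "age_c": float(participant["age"]) - 14.0,
        "sport_club": 1.0 if participant["sport_club"] == "yes" else 0.0,
        "low_ses": 1.0 if participant["ses"] == "low" else 0.0,
    }


def _linear_effect(participant, coeffs: dict) -> float:
    cov = effect_covariates(participant)
    return sum(beta * cov[name] for name, beta in coeffs.items())


# ---------------------------------------------------------------------------
# cohort-level generation

def generate_cohort(config: SimulationConfig, rng=None):
    """Generate the cohort, school and timetable tables.

    Returns ``(cohort, schools, timetables, pos_sites)``: demographics
    are drawn from the configured marginals, each participant gets a
    home coordinate in the study area and a school/class assignment;
    POS sites are scattered over the study area per category.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lat0, lat1, lon0, lon1 = config.study_area

    schools = pd.DataFrame(
        {
            "school_id": [f"S{i + 1}" for i in range(config.n_schools)],
            "lat": rng.uniform(lat0 + 0.01, lat1 - 0.01, config.n_schools),
            "lon": rng.uniform(lon0 + 0.01, lon1 - 0.01, config.n_schools),
        }
    )

    timetables: dict[str, ClassTimetable] = {}
    classes_per_school = 3
    hours = (dt.time(8, 30), dt.time(16, 0))
    recess = [(dt.time(10, 10), dt.time(10, 25)), (dt.time(12, 0), dt.time(12, 50))]
    for sid in schools["school_id"]:
        for c in range(classes_per_school):
            cid = f"{sid}_C{c + 1}"
            tt = ClassTimetable(sid, cid)
            pe_day = int(rng.integers(0, 5))
            for wd in range(5):
                pe = [(dt.time(14, 0), dt.time(15, 0))] if wd == pe_day else []
                tt.weekdays[wd] = DayTimetable(hours, pe, list(recess))
            timetables[cid] = tt

    sites = []
    for cat in POS_CATEGORIES:
        for _ in range(config.sites_per_category):
            sites.append(
                {
                    "pos_category": cat,
                    "lat": rng.uniform(lat0, lat1),
                    "lon": rng.uniform(lon0, lon1),
                }
            )
    pos_sites = pd.DataFrame(sites)

    n = config.n_participants
    school_idx = rng.integers(0, config.n_schools, n)
    class_idx = rng.integers(0, classes_per_school, n)
    school_lat = schools["lat"].to_numpy()[school_idx]
    school_lon = schools["lon"].to_numpy()[school_idx]
    home_dist = rng.uniform(400.0, 3000.0, n)
    home_bearing = rng.uniform(0.0, 2 * math.pi, n)
    home = [
        _offset_point(la, lo, d, b)
        for la, lo, d, b in zip(school_lat, school_lon, home_dist, home_bearing)
    ]
    edu_levels = list(config.education_probs)
    edu_p = np.asarray(list(config.education_probs.values()), dtype=float)
    res_levels = list(config.residence_probs)
    res_p = np.asarray(list(config.residence_probs.values()), dtype=float)
    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:04d}" for i in range(n)],
            "age": np.clip(rng.normal(config.age_mean, config.age_sd, n), 12.0, 16.0).round(1),
            "gender": np.where(rng.random(n) < config.girl_prob, "female", "male"),
            "ethnicity": np.where(
                rng.random(n) < config.non_western_prob,
                "non-western-European",
                "western-European",
            ),
            "education": rng.choice(edu_levels, size=n, p=edu_p / edu_p.sum()),
            "ses": np.where(rng.random(n) < config.low_ses_prob, "low", "high"),
            "sport_club": np.where(rng.random(n) < config.sport_club_prob, "yes", "no"),
            "residence": rng.choice(res_levels, size=n, p=res_p / res_p.sum()),
            "home_lat": [h[0] for h in home],
            "home_lon": [h[1] for h in home],
            "school_id": schools["school_id"].to_numpy()[school_idx],
            "class_id": [
                f"{schools['school_id'].iloc[s]}_C{c + 1}"
                for s, c in zip(school_idx, class_idx)
            ],
        }
    )
    return cohort, schools, timetables, pos_sites


def _generate_weather(config: SimulationConfig, dates, rng) -> pd.DataFrame:
    n = len(dates)
    wet = rng.random(n) < 0.5
    rain = np.where(wet, rng.exponential(0.8, n), 0.0).round(1)
    return pd.DataFrame(
        {
            "date": dates,
            "rain_mm": rain,
            "sun_min": np.clip(rng.normal(246.0, 60.0, n), 0.0, None).round(0),
            "temp_c": rng.normal(15.1, 3.0, n).round(1),
        }
    )


# ---------------------------------------------------------------------------
# one participant-day

def _trip_epochs(dist_m: float, speed_kmh: float) -> int:
    """Trip length in 30 s epochs: duration rounded up to the grid,
    never below 4 epochs (2 min) so trips survive smoothing."""
    minutes = (dist_m / 1000.0) / speed_kmh * 60.0
    return max(4, int(math.ceil(minutes * 2.0)))


def _mode_for_distance(dist_m: float) -> str:
    if dist_m <= 700.0:
        return "pedestrian"
    if dist_m <= 2500.0:
        return "bicycle"
    return "motorized"


def _sample_company(cfg: BehaviourConfig, rng) -> tuple:
    p = cfg.company_probs
    if rng.random() < p["alone"]:
        company = ["alone"]
    else:
        rest = 1.0 - p["alone"]
        company = [
            c
            for c in ("friends/classmates", "siblings/cousins", "parents/grandparents")
            if rng.random() < min(1.0, p[c] / rest)
        ]
        if not company:
            company = ["friends/classmates"]
    if rng.random() < p["organisation"]:
        company.append("organisation")
    return tuple(company)


def _sample_multi(items, probs, rng) -> tuple:
    probs = np.asarray(probs, dtype=float)
    main = rng.choice(len(items), p=probs / probs.sum())
    chosen = {items[main]}
    if rng.random() < 0.2:
        chosen.add(items[rng.choice(len(items), p=probs / probs.sum())])
    return tuple(sorted(chosen))


def generate_day(
    participant,
    date: dt.date,
    config: SimulationConfig,
    timetable: ClassTimetable | None,
    school,
    pos_sites: pd.DataFrame,
    rng,
    school_effect: float = 0.0,
):
    """Simulate one participant-day.

    Returns ``(truth, gps, counts, annotations)`` where ``truth`` is a
    dict with the day's segment list (tiling the wear window), the
    injected non-wear windows, and the day's true POS totals.
    """
    cfg = config.behaviour
    h0, m0 = map(int, cfg.wear_start.split(":"))
    h1, m1 = map(int, cfg.wear_end.split(":"))
    t0 = pd.Timestamp(dt.datetime.combine(date, dt.time(h0, m0)))
    n_epochs = int((dt.datetime.combine(date, dt.time(h1, m1)) - t0.to_pydatetime()).total_seconds() // EPOCH_S)

    home = (float(participant["home_lat"]), float(participant["home_lon"]))
    school_pt = (float(school["lat"]), float(school["lon"])) if school is not None else None
    weekday = date.weekday()
    is_school_day = timetable is not None and weekday in timetable.weekdays

    # --- schedule construction (epoch-indexed, ground truth) ---------------
    plan: list[dict] = []  # {n, domain, mode, pos_category, frm, to, annotated}

    def add(n, domain, loc, mode=None, frm=None, to=None, pos_category=None, annotated=False):
        if n > 0:
            plan.append(
                dict(n=int(n), domain=domain, mode=mode, loc=loc, frm=frm, to=to,
                     pos_category=pos_category, annotated=annotated)
            )

    def site_ok(lat, lon):
        if haversine_distance(lat, lon, home[0], home[1]) < 220.0:
            return False
        if school_pt and haversine_distance(lat, lon, school_pt[0], school_pt[1]) < 220.0:
            return False
        return True

    def pick_site(origin):
        cats = list(cfg.pos_category_probs)
        p = np.asarray(list(cfg.pos_category_probs.values()), dtype=float)
        cat = cats[rng.choice(len(cats), p=p / p.sum())]

        def usable(frame):
            ok = np.array([site_ok(r["lat"], r["lon"]) for _, r in frame.iterrows()])
            far = (
                haversine_distance(
                    frame["lat"].to_numpy(), frame["lon"].to_numpy(), origin[0], origin[1]
                )
                > 300.0
            )
            return frame[ok & far]

        pool = usable(pos_sites[pos_sites["pos_category"] == cat])
        if pool.empty:
            pool = usable(pos_sites)
        d = haversine_distance(
            pool["lat"].to_numpy(), pool["lon"].to_numpy(), origin[0], origin[1]
        )
        row = pool.iloc[int(np.argmin(d))]
        return row["pos_category"], (float(row["lat"]), float(row["lon"]))

    occ_logit = (
        math.log(cfg.pos_visit_prob / (1.0 - cfg.pos_visit_prob))
        + _linear_effect(participant, config.effects.occurrence)
        + school_effect
    )
    p_visit = 1.0 / (1.0 + math.exp(-occ_logit))
    short_day = rng.random() < cfg.short_day_prob
    visiting = (not short_day) and rng.random() < p_visit
    n_visits = 1 + int(rng.random() < cfg.extra_visit_prob) + int(
        rng.random() < cfg.extra_visit_prob
    ) if visiting else 0
    other_out = (
        not short_day and not visiting and rng.random() < cfg.other_leisure_prob
    )
    dwell_mult = math.exp(_linear_effect(participant, config.effects.amount))

    # morning / school block
    free_start = 0
    loc = home
    if is_school_day and school_pt is not None:
        day_tt = timetable.weekdays[weekday]
        sh0, sh1 = day_tt.school_hours
        start_epoch = int((dt.datetime.combine(date, sh0) - t0.to_pydatetime()).total_seconds() // EPOCH_S)
        end_epoch = int((dt.datetime.combine(date, sh1) - t0.to_pydatetime()).total_seconds() // EPOCH_S)
        d_hs = float(haversine_distance(home[0], home[1], school_pt[0], school_pt[1]))
        mode = _mode_for_distance(d_hs)
        trip_n = _trip_epochs(d_hs, cfg.mode_speed_kmh[mode])
        add(start_epoch - trip_n, "home", home)
        add(trip_n, "transport", None, mode=mode, frm=home, to=school_pt)
        add(end_epoch - start_epoch, "school", school_pt)
        free_start = end_epoch
        loc = school_pt
    else:
        # weekend: home until early afternoon
        free_start = int(rng.integers(600, 780))  # 12:30-14:00 after a 07:30 start
        if not visiting and not other_out:
            free_start = n_epochs
        add(free_start, "home", home)

    # afternoon itinerary
    budget = n_epochs - free_start
    itinerary: list[dict] = []
    if visiting:
        for _ in range(n_visits):
            cat, site = pick_site(loc)
            d = float(haversine_distance(loc[0], loc[1], site[0], site[1]))
            mode = _mode_for_distance(d)
            trip_n = _trip_epochs(d, cfg.mode_speed_kmh[mode])
            dwell_min = rng.gamma(
                cfg.dwell_shape, cfg.dwell_mean_min * dwell_mult / cfg.dwell_shape
            )
            dwell_n = max(4, int(round(dwell_min * 2.0)))
            itinerary.append(
                dict(kind="trip", n=trip_n, mode=mode, frm=loc, to=site)
            )
            itinerary.append(dict(kind="pos", n=dwell_n, loc=site, cat=cat))
            loc = site
    elif other_out and free_start < n_epochs:
        bearing = rng.uniform(0.0, 2.0 * math.pi)
        spot = _offset_point(home[0], home[1], rng.uniform(300.0, 1000.0), bearing)
        d = float(haversine_distance(home[0], home[1], spot[0], spot[1]))
        mode = _mode_for_distance(d)
        trip_n = _trip_epochs(d, cfg.mode_speed_kmh[mode])
        dwell_n = int(rng.integers(60, 120))
        itinerary.append(dict(kind="trip", n=trip_n, mode=mode, frm=home, to=spot))
        itinerary.append(dict(kind="other", n=dwell_n, loc=spot))
        loc = spot

    if loc != home:
        d = float(haversine_distance(loc[0], loc[1], home[0], home[1]))
        mode = _mode_for_distance(d)
        itinerary.append(
            dict(kind="trip", n=_trip_epochs(d, cfg.mode_speed_kmh[mode]),
                 mode=mode, frm=loc, to=home)
        )

    need = sum(item["n"] for item in itinerary)
    min_home_tail = 10  # keep at least 5 min at home at the day's end
    while need + min_home_tail > budget and itinerary:
        # day too short for the drawn itinerary: drop the last POS leg
        drop = [i for i, item in enumerate(itinerary) if item["kind"] in ("pos", "other")]
        if not drop:
            itinerary = []
            break
        k = drop[-1]
        del itinerary[k]          # the dwell
        del itinerary[k - 1]      # its inbound trip
        if itinerary and itinerary[-1]["kind"] == "trip":
            last_from = itinerary[k - 2]["loc"] if k >= 2 else home
            d = float(haversine_distance(last_from[0], last_from[1], home[0], home[1]))
            mode = _mode_for_distance(d)
            itinerary[-1] = dict(
                kind="trip", n=_trip_epochs(d, cfg.mode_speed_kmh[mode]),
                mode=mode, frm=last_from, to=home,
            )
            if len(itinerary) == 1:
                itinerary = []
        need = sum(item["n"] for item in itinerary)

    for item in itinerary:
        if item["kind"] == "trip":
            add(item["n"], "transport", None, mode=item["mode"], frm=item["frm"], to=item["to"])
        elif item["kind"] == "pos":
            add(item["n"], "leisure", item["loc"], pos_category=item["cat"], annotated=True)
        else:
            add(item["n"], "leisure", item["loc"])

    used = sum(p["n"] for p in plan)
    add(n_epochs - used, "home", home)

    # --- materialize epoch arrays ------------------------------------------
    lat = np.empty(n_epochs)
    lon = np.empty(n_epochs)
    context = np.empty(2 * n_epochs, dtype=object)
    cursor = 0
    truth_segments = []
    for seg in plan:
        n = seg["n"]
        sl = slice(cursor, cursor + n)
        if seg["domain"] == "transport":
            f = np.arange(n, dtype=float) / n
            lat[sl] = seg["frm"][0] + (seg["to"][0] - seg["frm"][0]) * f
            lon[sl] = seg["frm"][1] + (seg["to"][1] - seg["frm"][1]) * f
            ctx = f"trip_{seg['mode']}"
            context[2 * cursor: 2 * (cursor + n)] = ctx
        else:
            lat[sl] = seg["loc"][0]
            lon[sl] = seg["loc"][1]
            if seg["domain"] == "home":
                ctx = "home"
            elif seg["domain"] == "school":
                ctx = "school_class"
            elif seg["pos_category"] is not None:
                ctx = (
                    "pos_sports"
                    if seg["pos_category"] == "outdoor sports ground/playground"
                    else "pos"
                )
            else:
                ctx = "leisure_other"
            context[2 * cursor: 2 * (cursor + n)] = ctx
        truth_segments.append(
            dict(
                participant_id=participant["participant_id"],
                date=date,
                start=t0 + pd.Timedelta(seconds=EPOCH_S * cursor),
                end=t0 + pd.Timedelta(seconds=EPOCH_S * (cursor + n)),
                domain=seg["domain"],
                mode=seg["mode"],
                pos_category=seg["pos_category"],
                annotated=seg["annotated"],
            )
        )
        cursor += n

    # school sub-contexts from the timetable (PE / recess within hours)
    if is_school_day:
        day_tt = timetable.weekdays[weekday]
        times15 = t0 + pd.to_timedelta(np.arange(2 * n_epochs) * 15, unit="s")
        tod = pd.Series(times15).dt.time.to_numpy()
        at_school = context == "school_class"
        for blocks, label in ((day_tt.recess_blocks, "school_recess"), (day_tt.pe_blocks, "school_pe")):
            for b0, b1 in blocks:
                context[at_school & (tod >= b0) & (tod < b1)] = label

    counts = np.empty(2 * n_epochs, dtype=np.int64)
    for ctx in pd.unique(context):
        idx = np.flatnonzero(context == ctx)
        counts[idx] = _draw_counts(ctx, len(idx), cfg, rng)

    # non-wear injection: zero-count bout in the evening home stretch
    nonwear_windows = []
    if not short_day and rng.random() < cfg.nonwear_prob:
        dur_min = rng.uniform(*cfg.nonwear_min_range)
        dur_ep = int(round(dur_min * 2.0))
        tail = plan[-1]
        if tail["domain"] == "home" and tail["n"] >= dur_ep + 4:
            tail_start = n_epochs - tail["n"]
            s = int(rng.integers(tail_start + 2, n_epochs - dur_ep - 1))
            counts[2 * s: 2 * (s + dur_ep)] = 0
            # guard the boundaries so the injected run is exactly dur_ep epochs
            for j in (2 * s - 1, 2 * (s + dur_ep)):
                if counts[j] == 0:
                    counts[j] = 40
            nonwear_windows.append(
                (
                    t0 + pd.Timedelta(seconds=EPOCH_S * s),
                    t0 + pd.Timedelta(seconds=EPOCH_S * (s + dur_ep)),
                )
            )

    cut = n_epochs
    if short_day:
        # device taken off mid-afternoon: zero counts to the end of the
        # window (one long non-wear run) and no further GPS fixes
        cut = int(rng.integers(600, 1000))  # 5h-8h20 worn -> below the 9 h rule
        counts[2 * cut:] = 0
        if counts[2 * cut - 1] == 0:
            counts[2 * cut - 1] = 40
        nonwear_windows.append(
            (
                t0 + pd.Timedelta(seconds=EPOCH_S * cut),
                t0 + pd.Timedelta(seconds=EPOCH_S * n_epochs),
            )
        )

    if cfg.jitter_m > 0:
        lat = lat + rng.normal(0.0, cfg.jitter_m / DEG_LAT_M, n_epochs)
        lon = lon + rng.normal(
            0.0, cfg.jitter_m / (DEG_LAT_M * math.cos(math.radians(float(lat[0])))), n_epochs
        )

    fix_times = t0 + pd.to_timedelta(np.arange(n_epochs) * EPOCH_S, unit="s")
    keep = rng.random(n_epochs) >= cfg.gps_dropout_prob
    keep &= np.arange(n_epochs) < cut
    gps = pd.DataFrame(
        {
            "participant_id": participant["participant_id"],
            "timestamp": fix_times[keep],
            "lat": lat[keep],
            "lon": lon[keep],
            "elevation_m": np.round(10.0 + rng.normal(0.0, 1.5, int(keep.sum())), 1),
        }
    )
    counts_df = pd.DataFrame(
        {
            "participant_id": participant["participant_id"],
            "timestamp": t0 + pd.to_timedelta(np.arange(2 * n_epochs) * 15, unit="s"),
            "counts": counts,
        }
    )

    annotations = []
    for seg in truth_segments:
        if seg["annotated"]:
            annotations.append(
                {
                    "participant_id": seg["participant_id"],
                    "start": seg["start"],
                    "end": seg["end"],
                    "pos_category": seg["pos_category"],
                    "company": _sample_company(cfg, rng),
                    "reasons": _sample_multi(cfg.reasons, cfg.reason_probs, rng),
                    "activities": _sample_multi(cfg.activities, cfg.activity_probs, rng),
                }
            )
    ann_df = pd.DataFrame(
        annotations,
        columns=["participant_id", "start", "end", "pos_category", "company", "reasons", "activities"],
    )

    # --- true POS totals ----------------------------------------------------
    pos_idx = [i for i, s in enumerate(truth_segments) if s["pos_category"] is not None]
    attributed: set[int] = set()
    for i in pos_idx:
        if i > 0 and truth_segments[i - 1]["domain"] == "transport":
            attributed.add(i - 1)
        if i + 1 < len(truth_segments) and truth_segments[i + 1]["domain"] == "transport":
            attributed.add(i + 1)
    include = sorted(set(pos_idx) | attributed)
    pos_min = 0.0
    pos_intensity = {"st": 0.0, "lpa": 0.0, "mpa": 0.0, "vpa": 0.0}
    codes = classify_intensity(counts)
    for i in include:
        s = truth_segments[i]
        e0 = int((s["start"] - t0).total_seconds() // 15)
        e1 = int((s["end"] - t0).total_seconds() // 15)
        pos_min += (e1 - e0) * 0.25
        for c, k in enumerate(("st", "lpa", "mpa", "vpa")):
            pos_intensity[k] += 0.25 * float(np.sum(codes[e0:e1] == c))

    truth = {
        "segments": truth_segments,
        "nonwear_windows": nonwear_windows,
        "n_visits": len(pos_idx),
        "pos_categories": [truth_segments[i]["pos_category"] for i in pos_idx],
        "company": [a["company"] for a in annotations],
        "pos_min": pos_min,
        "pos_intensity_min": pos_intensity,
        "wear_min": n_epochs * 0.5
        - sum((b - a).total_seconds() / 60.0 for a, b in nonwear_windows),
    }
    return truth, gps, counts_df, ann_df


# ---------------------------------------------------------------------------
# whole dataset

def generate_dataset(config: SimulationConfig) -> dict:
    """Generate the full cohort dataset plus ground truth.

    Per-participant random streams come from counter-based children of
    the master seed, so each participant's data is reproducible
    independent of generation order.
    """
    config.validate()
    cohort, schools, timetables, pos_sites = generate_cohort(config)
    rng_misc = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    # schools are measured in staggered weekly waves, as in a rolling
    # school-by-school field campaign; weather then varies across the cohort
    base = dt.date.fromisoformat(config.start_date)
    dates_by_school = {
        sid: [
            base + dt.timedelta(days=7 * (i % 4) + k)
            for k in range(config.n_days)
        ]
        for i, sid in enumerate(schools["school_id"])
    }
    all_dates = sorted({d for ds_ in dates_by_school.values() for d in ds_})
    weather = _generate_weather(config, all_dates, rng_misc)
    school_effects = {
        sid: config.school_sigma * float(z)
        for sid, z in zip(schools["school_id"], rng_misc.normal(size=len(schools)))
    }
    schools_by_id = {r["school_id"]: r for _, r in schools.iterrows()}

    gps_parts, count_parts, ann_parts = [], [], []
    truth_days = []
    for i, (_, participant) in enumerate(cohort.iterrows()):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, i]))
        tt = timetables.get(participant["class_id"])
        school = schools_by_id.get(participant["school_id"])
        for date in dates_by_school[participant["school_id"]]:
            truth, gps, counts, anns = generate_day(
                participant, date, config, tt, school, pos_sites, rng,
                school_effects[participant["school_id"]],
            )
            gps_parts.append(gps)
            count_parts.append(counts)
            if len(anns):
                ann_parts.append(anns)
            truth_days.append(
                {
                    "participant_id": participant["participant_id"],
                    "date": date,
                    **{k: truth[k] for k in ("n_visits", "pos_min", "wear_min")},
                    "pos_categories": truth["pos_categories"],
                    "company": truth["company"],
                    "pos_intensity_min": truth["pos_intensity_min"],
                    "segments": truth["segments"],
                    "nonwear_windows": truth["nonwear_windows"],
                }
            )
    return {
        "config": config,
        "cohort": cohort,
        "schools": schools,
        "timetables": timetables,
        "pos_sites": pos_sites,
        "weather": weather,
        "school_effects": school_effects,
        "gps": pd.concat(gps_parts, ignore_index=True),
        "counts": pd.concat(count_parts, ignore_index=True),
        "annotations": (
            pd.concat(ann_parts, ignore_index=True)
            if ann_parts
            else pd.DataFrame(
                columns=["participant_id", "start", "end", "pos_category",
                         "company", "reasons", "activities"]
            )
        ),
        "truth_days": truth_days,
    }


def write_dataset(dataset: dict, directory) -> dict[str, Path]:
    """Write the six pipeline input files plus the ground-truth file.

    The ground-truth files carry the ``ground_truth`` filename prefix
    and are never read by the pipeline.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gps": directory / "gps.csv",
        "counts": directory / "counts.csv",
        "cohort": directory / "cohort.csv",
        "schools": directory / "schools.csv",
        "timetables": directory / "timetables.yaml",
        "annotations": directory / "annotations.csv",
        "weather": directory / "weather.csv",
        "ground_truth": directory / f"{GROUND_TRUTH_PREFIX}_days.csv",
    }
    write_gps_log(dataset["gps"], paths["gps"])
    write_count_log(dataset["counts"], paths["counts"])
    write_cohort(dataset["cohort"], paths["cohort"])
    write_schools(dataset["schools"], paths["schools"])
    write_timetables(dataset["timetables"], paths["timetables"])
    write_annotations(dataset["annotations"], paths["annotations"])
    write_weather(dataset["weather"], paths["weather"])
    truth = pd.DataFrame(
        [
            {
                "participant_id": d["participant_id"],
                "date": d["date"],
                "n_visits": d["n_visits"],
                "pos_min": d["pos_min"],
                "wear_min": d["wear_min"],
            }
            for d in dataset["truth_days"]
        ]
    )
    truth.to_csv(paths["ground_truth"], index=False)
    return paths
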