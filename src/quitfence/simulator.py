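"""Synthetic smoker cohort: mobility traces, episodes, reports, surveys.

Each simulated user lives a multi-anchor daily routine (home, work on
weekdays, a social venue some evenings, with commute gaps in between) and
smokes at those anchors. The generator separates *ground truth* (every
smoking episode, with its true time, place and context) from what the app
would actually observe:

* only a fraction of episodes become real-time reports
  (``report_compliance_p``, default 0.55 — smokers who self-initiate logging
  record roughly half of what they smoke);
* a report's location fix can fail (``location_capture_p``, default 0.97);
* captured positions carry GPS noise: the reported accuracy is drawn
  log-normal with mean ≈ 31.6 m / SD ≈ 16.8 m, and the positional error is
  an isotropic 2-D Gaussian whose 68% containment radius equals that
  accuracy value;
* end-of-day diaries are completed with probability 0.60 pre-quit / 0.39
  post-quit, recording the *true* daily count as a category — which is what
  makes under-reporting measurable;
* notification opens are delayed log-normally (median 23.6 min) with a
  never-open probability ≈ 0.26, tuned so about half of all notifications
  are opened within 30 minutes; opened messages are rated with
  probability 0.78.

All randomness flows from the scenario seed through per-user substreams,
so any single user is reproducible in isolation.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .geo import GeoPoint, LocationSample, destination
from .metrics import DEFAULT_BOUNDS
from .reporting import (
    Company,
    EoDSurvey,
    Situation,
    SmokingReport,
    Stage,
    UserProfile,
    local_date,
    stage_of,
)
from .trigger_engine import TriggerEvent

# 68% of a 2-D isotropic Gaussian lies within r = sigma * sqrt(2*ln(1/0.32)).
_SIGMA_PER_ACCURACY = 1.0 / math.sqrt(2.0 * math.log(1.0 / 0.32))

_H = 3600.0


@dataclass
class SimScenario:
    seed: int = 0
    n_users: int = 15
    pre_quit_days: int = 20
    post_quit_days: int = 28
    sampling_interval_min: float = 15.0
    # True smoking intensity per anchor (episodes/day while the anchor is
    # in that day's schedule); the weekday/weekend schedule thins work and
    # social exposure so the realized situation mix lands near
    # home 50% / work 31% / social 6% / other 13%.
    episodes_per_day: dict[str, float] = field(
        default_factory=lambda: {"home": 2.0, "work": 1.55, "social": 0.8, "other": 0.5}
    )
    report_compliance_p: float = 0.55
    location_capture_p: float = 0.97
    accuracy_mean_m: float = 31.6
    accuracy_sd_m: float = 16.8
    eod_completion_p_pre: float = 0.60
    eod_completion_p_post: float = 0.39
    open_delay_median_min: float = 23.6
    open_delay_sigma: float = 0.519
    never_open_p: float = 0.263
    rating_p: float = 0.78
    lapse_p: float = 0.5
    post_quit_episodes_per_day: float = 0.4
    tz_offset_min: int = 0
    study_start: _dt.date = _dt.date(2016, 3, 7)  # a Monday
    base_lat: float = 52.2
    base_lon: float = 0.12

    def __post_init__(self) -> None:
        for name in (
            "report_compliance_p",
            "location_capture_p",
            "eod_completion_p_pre",
            "eod_completion_p_post",
            "never_open_p",
            "rating_p",
            "lapse_p",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")

    @property
    def total_days(self) -> int:
        return self.pre_quit_days + self.post_quit_days

    def accuracy_lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal matching the accuracy mean/SD."""
        cv2 = (self.accuracy_sd_m / self.accuracy_mean_m) ** 2
        sigma2 = math.log(1.0 + cv2)
        mu = math.log(self.accuracy_mean_m) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)


@dataclass
class GroundTruth:
    """What actually happened, for parameter-recovery testing."""

    anchors: dict[str, GeoPoint]
    episodes: list[tuple[float, str, GeoPoint]]  # (timestamp, anchor label, true position)
    daily_counts: dict[_dt.date, int]


@dataclass
class UserSim:
    profile: UserProfile
    ground_truth: GroundTruth
    trace: list[LocationSample]
    reports: list[SmokingReport]
    eods: list[EoDSurvey]


@dataclass
class Cohort:
    scenario: SimScenario
    users: list[UserSim]

    @property
    def manifest(self) -> dict:
        s = self.scenario
        return {
            "seed": s.seed,
            "n_users": s.n_users,
            "pre_quit_days": s.pre_quit_days,
            "post_quit_days": s.post_quit_days,
            "report_compliance_p": s.report_compliance_p,
            "location_capture_p": s.location_capture_p,
            "eod_completion_p_pre": s.eod_completion_p_pre,
            "eod_completion_p_post": s.eod_completion_p_post,
            "rating_p": s.rating_p,
            "never_open_p": s.never_open_p,
            "study_start": s.study_start.isoformat(),
        }


# Anchor-conditional context distributions (probabilities over scale 1..5,
# urges 0..5). Stress skews high at work, low while socializing.
_STRESS_P = {
    "home": (0.10, 0.20, 0.35, 0.25, 0.10),
    "work": (0.03, 0.10, 0.25, 0.37, 0.25),
    "social": (0.25, 0.35, 0.25, 0.10, 0.05),
    "other": (0.15, 0.25, 0.30, 0.20, 0.10),
}
_MOOD_P = {
    "home": (0.05, 0.15, 0.35, 0.30, 0.15),
    "work": (0.10, 0.25, 0.35, 0.20, 0.10),
    "social": (0.02, 0.08, 0.25, 0.35, 0.30),
    "other": (0.08, 0.20, 0.35, 0.25, 0.12),
}
_URGE_P = (0.05, 0.10, 0.15, 0.25, 0.25, 0.20)  # 0..5, shared
_COMPANY_P = {
    "home": ((Company.ALONE, 0.60), (Company.FRIENDS_FAMILY, 0.35), (Company.OTHERS, 0.05)),
    "work": ((Company.COLLEAGUES, 0.60), (Company.ALONE, 0.30), (Company.OTHERS, 0.10)),
    "social": ((Company.FRIENDS_FAMILY, 0.70), (Company.OTHERS, 0.30)),
    "other": ((Company.ALONE, 0.50), (Company.FRIENDS_FAMILY, 0.25), (Company.OTHERS, 0.25)),
}
_OTHERS_SMOKING_P = {"home": 0.3, "work": 0.4, "social": 0.6, "other": 0.3}
_SITUATION_OF_ANCHOR = {
    "home": Situation.HOME,
    "work": Situation.WORKING,
    "social": Situation.SOCIALIZING,
    "other": Situation.OTHER,
}


def _day_blocks(
    day: _dt.date, social_weekdays: frozenset[int]
) -> list[tuple[str, float, float]]:
    """Ordered (anchor, start_s, end_s) dwell blocks for one local day."""
    wd = day.weekday()
    blocks: list[tuple[str, float, float]]
    if wd < 5:
        blocks = [
            ("home", 0.0, 8.0 * _H),
            ("commute", 8.0 * _H, 8.5 * _H),
            ("work", 8.5 * _H, 17.0 * _H),
            ("commute", 17.0 * _H, 17.5 * _H),
        ]
        evening_start = 17.5 * _H
    else:
        blocks = []
        evening_start = 0.0
    if wd in social_weekdays:
        blocks += [
            ("home", evening_start, 19.0 * _H),
            ("social", 19.0 * _H, 22.0 * _H),
            ("home", 22.0 * _H, 24.0 * _H),
        ]
    else:
        blocks.append(("home", evening_start, 24.0 * _H))
    return blocks


def _noisy_point(rng: np.random.Generator, true: GeoPoint, accuracy_m: float) -> GeoPoint:
    r = rng.rayleigh(accuracy_m * _SIGMA_PER_ACCURACY)
    return destination(true, float(rng.uniform(0.0, 360.0)), float(r))


def _draw_context(rng: np.random.Generator, anchor: str) -> dict:
    stress = int(rng.choice(5, p=_STRESS_P[anchor])) + 1
    mood = int(rng.choice(5, p=_MOOD_P[anchor])) + 1
    urge = int(rng.choice(6, p=_URGE_P))
    companies, weights = zip(*_COMPANY_P[anchor])
    company = companies[int(rng.choice(len(companies), p=np.array(weights)))]
    others = None
    if company is not Company.ALONE:
        others = bool(rng.random() < _OTHERS_SMOKING_P[anchor])
    return {
        "stress": stress,
        "mood": mood,
        "urge_strength": urge,
        "company": company,
        "others_smoking": others,
        "situation": _SITUATION_OF_ANCHOR[anchor],
    }


def _make_profile(rng: np.random.Generator, scenario: SimScenario, idx: int) -> UserProfile:
    return UserProfile(
        user_id=f"user-{idx:03d}",
        quit_date=scenario.study_start + _dt.timedelta(days=scenario.pre_quit_days),
        gender=str(rng.choice(["male", "female"])),
        age_band=str(rng.choice(["18-24", "25-34", "35-44", "45+"], p=[0.15, 0.35, 0.3, 0.2])),
        cigarettes_per_day_band=str(
            rng.choice(["1-5", "6-10", "11-15", "16-20", "21+"], p=[0.1, 0.45, 0.25, 0.15, 0.05])
        ),
        first_cigarette_within_30min=bool(rng.random() < 0.5),
        lives_with_smokers=bool(rng.random() < 0.4),
        plans_ecigarette=bool(rng.random() < 0.33),
    )


def simulate_user(scenario: SimScenario, user_index: int) -> UserSim:
    """Generate one user's profile, ground truth, trace, reports and diaries.

    Fully reproducible from ``(scenario.seed, user_index)``.
    """
    rng = np.random.default_rng([scenario.seed, user_index])
    profile = _make_profile(rng, scenario, user_index)
    base = GeoPoint(scenario.base_lat, scenario.base_lon)
    home = destination(base, float(rng.uniform(0, 360)), float(rng.uniform(0, 8000)))
    work = destination(home, float(rng.uniform(0, 360)), float(rng.uniform(1000, 5000)))
    social = destination(home, float(rng.uniform(0, 360)), float(rng.uniform(500, 3000)))
    anchors = {"home": home, "work": work, "social": social}
    social_weekdays = frozenset(rng.choice(7, size=2, replace=False).tolist())
    tz = scenario.tz_offset_min
    mu, sigma = scenario.accuracy_lognormal_params()

    def day_start_ts(day: _dt.date) -> float:
        midnight_local = _dt.datetime.combine(day, _dt.time(0), tzinfo=_dt.timezone.utc)
        return midnight_local.timestamp() - tz * 60

    def position_at(day: _dt.date, sec_of_day: float) -> Optional[GeoPoint]:
        for anchor, start, end in _day_blocks(day, social_weekdays):
            if start <= sec_of_day < end:
                if anchor == "commute":
                    frac = (sec_of_day - start) / (end - start)
                    if start < 12 * _H:  # morning: home -> work
                        a, b = home, work
                    else:
                        a, b = work, home
                    return GeoPoint(
                        a.lat + frac * (b.lat - a.lat), a.lon + frac * (b.lon - a.lon)
                    )
                return anchors[anchor]
        return anchors["home"]

    # --- background trace ---------------------------------------------------
    step = scenario.sampling_interval_min * 60.0
    trace: list[LocationSample] = []
    t0 = day_start_ts(scenario.study_start)
    n_samples = int(scenario.total_days * 24 * _H / step)
    for k in range(n_samples):
        ts = t0 + k * step
        day = local_date(ts, tz)
        sec = ts - day_start_ts(day)
        true_pos = position_at(day, sec)
        acc = float(rng.lognormal(mu, sigma))
        trace.append(LocationSample(ts, _noisy_point(rng, true_pos, acc), acc))

    # --- smoking episodes ---------------------------------------------------
    episodes: list[tuple[float, str, GeoPoint]] = []
    daily_counts: dict[_dt.date, int] = {}
    lapses = bool(rng.random() < scenario.lapse_p)
    lapse_start_day = int(rng.integers(1, 18)) if lapses else None
    for d in range(scenario.total_days):
        day = scenario.study_start + _dt.timedelta(days=d)
        ds = day_start_ts(day)
        blocks = _day_blocks(day, social_weekdays)
        day_eps: list[tuple[float, str, GeoPoint]] = []
        if d < scenario.pre_quit_days:
            for anchor, lam in scenario.episodes_per_day.items():
                if anchor == "other":
                    for _ in range(rng.poisson(lam)):
                        sec = float(rng.uniform(8 * _H, 22 * _H))
                        pos = destination(
                            home, float(rng.uniform(0, 360)), float(rng.uniform(200, 2000))
                        )
                        day_eps.append((ds + sec, "other", pos))
                    continue
                spans = [(s, e) for a, s, e in blocks if a == anchor]
                if not spans:
                    continue
                durations = np.array([e - s for s, e in spans])
                for _ in range(rng.poisson(lam)):
                    s, e = spans[int(rng.choice(len(spans), p=durations / durations.sum()))]
                    day_eps.append((ds + float(rng.uniform(s, e)), anchor, anchors[anchor]))
        elif lapses and d - scenario.pre_quit_days >= lapse_start_day:
            for _ in range(rng.poisson(scenario.post_quit_episodes_per_day)):
                anchor = str(rng.choice(["work", "home", "other"], p=[0.68, 0.27, 0.05]))
                if anchor == "other":
                    pos = destination(
                        home, float(rng.uniform(0, 360)), float(rng.uniform(200, 2000))
                    )
                    sec = float(rng.uniform(8 * _H, 22 * _H))
                else:
                    spans = [(s, e) for a, s, e in blocks if a == anchor]
                    if not spans:
                        spans = [(0.0, 24 * _H)]
                    s, e = spans[int(rng.integers(len(spans)))]
                    sec = float(rng.uniform(s, e))
                    pos = anchors[anchor]
                day_eps.append((ds + sec, anchor, pos))
        day_eps.sort(key=lambda t: t[0])
        episodes.extend(day_eps)
        daily_counts[day] = len(day_eps)

    # --- reports (partial compliance, noisy location) -----------------------
    reports: list[SmokingReport] = []
    for j, (ts, anchor, pos) in enumerate(episodes):
        if rng.random() >= scenario.report_compliance_p:
            continue
        ctx = _draw_context(rng, anchor)
        located = rng.random() < scenario.location_capture_p
        acc = float(rng.lognormal(mu, sigma)) if located else None
        reports.append(
            SmokingReport(
                report_id=f"{profile.user_id}-r{j:04d}",
                timestamp=ts,
                mood=ctx["mood"],
                stress=ctx["stress"],
                urge_strength=ctx["urge_strength"],
                situation=ctx["situation"],
                company=ctx["company"],
                others_smoking=ctx["others_smoking"],
                location=_noisy_point(rng, pos, acc) if located else None,
                accuracy_m=acc,
                stage_at_report=stage_of(ts, profile, tz),
            )
        )

    # --- end-of-day diaries -------------------------------------------------
    eods: list[EoDSurvey] = []
    for d in range(scenario.total_days):
        day = scenario.study_start + _dt.timedelta(days=d)
        p = (
            scenario.eod_completion_p_pre
            if d < scenario.pre_quit_days
            else scenario.eod_completion_p_post
        )
        if rng.random() < p:
            eods.append(
                EoDSurvey(
                    user_id=profile.user_id,
                    local_date=day,
                    cigarettes_category=DEFAULT_BOUNDS.category_for(daily_counts[day]),
                    urge_strength=int(rng.integers(0, 6)),
                    urge_frequency=int(rng.integers(0, 6)),
                    abstinence_self_efficacy=int(rng.integers(1, 6)),
                )
            )

    return UserSim(
        profile=profile,
        ground_truth=GroundTruth(anchors=anchors, episodes=episodes, daily_counts=daily_counts),
        trace=trace,
        reports=reports,
        eods=eods,
    )


def simulate_interactions(
    events: Sequence[TriggerEvent],
    scenario: SimScenario,
    seed: int,
    select: Optional[Callable[[TriggerEvent], str]] = None,
) -> list[TriggerEvent]:
    """Attach simulated opens, message deliveries and ratings to events.

    Each event is opened with probability ``1 - never_open_p`` after a
    log-normal delay; opening delivers a message (``select`` maps the event
    to a message id, defaulting to a placeholder), which is then rated with
    probability ``rating_p``.
    """
    rng = np.random.default_rng([seed, 0x5EED])
    mu = math.log(scenario.open_delay_median_min * 60.0)
    out: list[TriggerEvent] = []
    for e in events:
        if rng.random() < scenario.never_open_p:
            out.append(e)
            continue
        delay = float(rng.lognormal(mu, scenario.open_delay_sigma))
        msg_id = select(e) if select is not None else f"sim-msg-{e.event_id}"
        rating = int(rng.integers(1, 6)) if rng.random() < scenario.rating_p else None
        out.append(
            replace(
                e,
                opened_at=e.generated_at + delay,
                message_id=msg_id,
                rating=rating,
            )
        )
    return out


def simulate_cohort(scenario: SimScenario) -> Cohort:
    """Generate the full cohort (traces, reports, diaries, ground truth)."""
    return Cohort(
        scenario=scenario,
        users=[simulate_user(scenario, i) for i in range(scenario.n_users)],
    )


__all__ = [
    "SimScenario",
    "GroundTruth",
    "UserSim",
    "Cohort",
    "simulate_user",
    "simulate_interactions",
    "simulate_cohort",
]
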