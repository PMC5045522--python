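"""Self-report data capture and intervention-stage resolution.

The intervention has three stages anchored on the user-nominated quit date:

* ``PREPARE_AND_LEARN`` — everything strictly before local midnight of the
  quit date; the user logs each cigarette as they smoke it and the engine
  learns their smoking locations.
* ``COMMIT_TO_QUIT`` — local days 0..27 from the quit date (a 28-day
  window); geofence-triggered support is active.
* ``MAINTAIN_THE_CHANGE`` — day 28 onward.

Each real-time smoking report carries a five-item context assessment:
mood (1-5), stress (1-5), urge strength (0-5, adapted from the Mood and
Physical Symptoms Scale), the current situation (Home / Working /
Socializing / Other), and who is present (and, unless alone, whether they
are smoking). Day bucketing uses a per-user local-timezone offset because
end-of-day surveys are daily diaries.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .geo import GeoPoint


class Stage(str, Enum):
    PREPARE_AND_LEARN = "PREPARE_AND_LEARN"
    COMMIT_TO_QUIT = "COMMIT_TO_QUIT"
    MAINTAIN_THE_CHANGE = "MAINTAIN_THE_CHANGE"


class Situation(str, Enum):
    HOME = "Home"
    WORKING = "Working"
    SOCIALIZING = "Socializing"
    OTHER = "Other"


class Company(str, Enum):
    ALONE = "Alone"
    FRIENDS_FAMILY = "FriendsFamily"
    COLLEAGUES = "Colleagues"
    OTHERS = "Others"


COMMIT_WINDOW_DAYS = 28

AGE_BANDS = ("18-24", "25-34", "35-44", "45+")
CPD_BANDS = ("1-5", "6-10", "11-15", "16-20", "21+")
EOD_CATEGORIES = ("0", "1-5", "6-10", "11-15", "16-20", "21+")

# Scale bounds are configuration constants (the instrument anchors are not
# part of the schema): mood/stress 1-5, urges 0-5.
MOOD_BOUNDS = (1, 5)
STRESS_BOUNDS = (1, 5)
URGE_BOUNDS = (0, 5)


class ValidationError(ValueError):
    """A raw record failed schema validation."""


@dataclass
class UserProfile:
    """Quit date plus the demographics/smoking survey used for tailoring.

    The seven characteristics below are fixed schema; any further survey
    items live in ``extra_items`` so tailoring keys stay extensible.
    """

    user_id: str
    quit_date: Optional[_dt.date] = None
    gender: Optional[str] = None
    age_band: Optional[str] = None
    cigarettes_per_day_band: Optional[str] = None
    first_cigarette_within_30min: Optional[bool] = None
    lives_with_smokers: Optional[bool] = None
    plans_ecigarette: Optional[bool] = None
    extra_items: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_band is not None and self.age_band not in AGE_BANDS:
            raise ValidationError(f"unknown age band {self.age_band!r}")
        if (
            self.cigarettes_per_day_band is not None
            and self.cigarettes_per_day_band not in CPD_BANDS
        ):
            raise ValidationError(
                f"unknown cigarettes-per-day band {self.cigarettes_per_day_band!r}"
            )

    def as_tailoring_keys(self) -> dict[str, str]:
        """Flatten the profile into the string key/value map messages match on."""
        keys: dict[str, str] = {}
        for name in (
            "gender",
            "age_band",
            "cigarettes_per_day_band",
            "first_cigarette_within_30min",
            "lives_with_smokers",
            "plans_ecigarette",
        ):
            value = getattr(self, name)
            if value is not None:
                keys[name] = str(value)
        keys.update(self.extra_items)
        return keys


@dataclass
class SmokingReport:
    """A validated self-initiated smoking log entry."""

    report_id: str
    timestamp: float
    mood: int
    stress: int
    urge_strength: int
    situation: Situation
    company: Company
    others_smoking: Optional[bool] = None
    location: Optional[GeoPoint] = None
    accuracy_m: Optional[float] = None
    stage_at_report: Stage = Stage.PREPARE_AND_LEARN

    def __post_init__(self) -> None:
        self.situation = Situation(self.situation)
        self.company = Company(self.company)
        self.stage_at_report = Stage(self.stage_at_report)
        _check_scale("mood", self.mood, MOOD_BOUNDS)
        _check_scale("stress", self.stress, STRESS_BOUNDS)
        _check_scale("urge_strength", self.urge_strength, URGE_BOUNDS)
        if self.company is Company.ALONE:
            if self.others_smoking is not None:
                raise ValidationError("others_smoking must be absent when company=Alone")
        elif self.others_smoking is None:
            raise ValidationError("others_smoking required when company != Alone")
        if (self.location is None) != (self.accuracy_m is None):
            raise ValidationError("location and accuracy_m must be present together")
        if self.accuracy_m is not None and self.accuracy_m < 0:
            raise ValidationError(f"accuracy_m must be >= 0, got {self.accuracy_m}")


@dataclass
class EoDSurvey:
    """End-of-day diary: categorical cigarette count, urges, self-efficacy."""

    user_id: str
    local_date: _dt.date
    cigarettes_category: str
    urge_strength: int
    urge_frequency: int
    abstinence_self_efficacy: int

    def __post_init__(self) -> None:
        if self.cigarettes_category not in EOD_CATEGORIES:
            raise ValidationError(
                f"unknown EoD cigarettes category {self.cigarettes_category!r}"
            )
        _check_scale("urge_strength", self.urge_strength, URGE_BOUNDS)
        _check_scale("urge_frequency", self.urge_frequency, URGE_BOUNDS)


def _check_scale(name: str, value: int, bounds: tuple[int, int]) -> None:
    lo, hi = bounds
    if not isinstance(value, int) or isinstance(value, bool) or not lo <= value <= hi:
        raise ValidationError(f"{name}={value!r} outside [{lo}, {hi}]")


_REQUIRED_ASSESSMENT = ("mood", "stress", "urge_strength", "situation", "company")


def validate_report(raw: Mapping[str, object]) -> SmokingReport:
    """Validate a raw record into a :class:`SmokingReport`.

    Location may legitimately be absent (a location-capture failure); the
    five assessment answers may not.
    """
    missing = [k for k in _REQUIRED_ASSESSMENT if raw.get(k) is None]
    if missing:
        raise ValidationError(f"missing assessment field(s): {', '.join(missing)}")
    location = None
    accuracy = None
    if raw.get("lat") is not None and raw.get("lon") is not None:
        location = GeoPoint(float(raw["lat"]), float(raw["lon"]))
        accuracy = float(raw.get("accuracy_m", 0.0))
    return SmokingReport(
        report_id=str(raw.get("report_id", "")),
        timestamp=float(raw["timestamp"]),
        mood=int(raw["mood"]),
        stress=int(raw["stress"]),
        urge_strength=int(raw["urge_strength"]),
        situation=Situation(raw["situation"]),
        company=Company(raw["company"]),
        others_smoking=raw.get("others_smoking"),
        location=location,
        accuracy_m=accuracy,
        stage_at_report=Stage(raw.get("stage_at_report", Stage.PREPARE_AND_LEARN)),
    )


def local_date(timestamp: float, tz_offset_min: int = 0) -> _dt.date:
    """User-local calendar date of a UTC epoch timestamp."""
    instant = _dt.datetime.fromtimestamp(timestamp, tz=_dt.timezone.utc)
    return (instant + _dt.timedelta(minutes=tz_offset_min)).date()


def stage_of(timestamp: float, profile: UserProfile, tz_offset_min: int = 0) -> Stage:
    """Resolve the intervention stage at an instant.

    The quit window opens at local midnight of the quit date and covers
    exactly ``COMMIT_WINDOW_DAYS`` local days (days 0..27 inclusive).
    """
    if profile.quit_date is None:
        raise ValueError(f"user {profile.user_id}: quit_date not set")
    day = (local_date(timestamp, tz_offset_min) - profile.quit_date).days
    if day < 0:
        return Stage.PREPARE_AND_LEARN
    if day < COMMIT_WINDOW_DAYS:
        return Stage.COMMIT_TO_QUIT
    return Stage.MAINTAIN_THE_CHANGE


def reports_per_day(
    reports: Iterable[SmokingReport],
    period: tuple[_dt.date, _dt.date],
    tz_offset_min: int = 0,
) -> pd.DataFrame:
    """Daily report counts over a closed date interval, zero-filled.

    Returns a DataFrame with columns ``local_date`` and ``count``, one row
    per day of ``period``; reports outside the period are ignored.
    """
    start, end = period
    if end < start:
        raise ValueError(f"empty period: {start} .. {end}")
    days = pd.date_range(start, end, freq="D").date
    counts = {d: 0 for d in days}
    for r in reports:
        d = local_date(r.timestamp, tz_offset_min)
        if start <= d <= end:
            counts[d] += 1
    return pd.DataFrame({"local_date": list(counts.keys()), "count": list(counts.values())})


__all__ = [
    "Stage",
    "Situation",
    "Company",
    "COMMIT_WINDOW_DAYS",
    "AGE_BANDS",
    "CPD_BANDS",
    "EOD_CATEGORIES",
    "ValidationError",
    "UserProfile",
    "SmokingReport",
    "EoDSurvey",
    "validate_report",
    "local_date",
    "stage_of",
    "reports_per_day",
]
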