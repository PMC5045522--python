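"""Feasibility metrics: compliance, capture, delivery, engagement.

Everything a feasibility read-out of the engine needs, computed from the
validated data types: self-report volume, situation mix, under-reporting
relative to the end-of-day diary, location-capture quality, geofence yield,
survey compliance, message delivery/rating rates, and the notification
response-time distribution.

Conventions: percentages round half-up to one decimal (two for the overall
message-rating rate); standard deviations use the n-1 sample estimator; a
day counts as under-reported when its real-time report count falls below
the lower bound of that day's end-of-day cigarette category — the
conservative reading, since such a day is certainly under-reported
whatever the true count inside the category.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .geo import Geofence
from .reporting import (
    EOD_CATEGORIES,
    EoDSurvey,
    Situation,
    SmokingReport,
    UserProfile,
    local_date,
)
from .tailoring import round_half_up
from .trigger_engine import EventType, TriggerEvent


@dataclass(frozen=True)
class CategoryBounds:
    """Integer bounds of the categorical cigarettes-per-day bands."""

    bounds: Mapping[str, tuple[int, Optional[int]]] = field(
        default_factory=lambda: {
            "0": (0, 0),
            "1-5": (1, 5),
            "6-10": (6, 10),
            "11-15": (11, 15),
            "16-20": (16, 20),
            "21+": (21, None),
        }
    )

    def lower(self, category: str) -> int:
        try:
            return self.bounds[category][0]
        except KeyError:
            raise ValueError(f"unknown category label {category!r}") from None

    def category_for(self, count: int) -> str:
        if count < 0:
            raise ValueError("count must be >= 0")
        for label, (lo, hi) in self.bounds.items():
            if count >= lo and (hi is None or count <= hi):
                return label
        raise ValueError(f"no category covers count {count}")


DEFAULT_BOUNDS = CategoryBounds()


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def _pct(n: int, total: int, decimals: int = 1) -> float:
    return round_half_up(100.0 * n / total, decimals) if total else 0.0


def underreporting_days(
    reports: Sequence[SmokingReport],
    eods: Sequence[EoDSurvey],
    bounds: CategoryBounds = DEFAULT_BOUNDS,
    tz_offset_min: int = 0,
) -> tuple[int, int, float]:
    """Days whose real-time report count undershoots the diary category.

    ``eods`` should already be restricted to the period of interest; each
    completed survey contributes one day to the denominator.
    """
    counts: dict[_dt.date, int] = {}
    for r in reports:
        d = local_date(r.timestamp, tz_offset_min)
        counts[d] = counts.get(d, 0) + 1
    under = sum(
        1 for s in eods if counts.get(s.local_date, 0) < bounds.lower(s.cigarettes_category)
    )
    total = len(eods)
    return under, total, _pct(under, total)


def eod_compliance(
    eods: Sequence[EoDSurvey],
    period: tuple[_dt.date, _dt.date],
    expected_per_day: int = 1,
) -> tuple[int, int, float]:
    """Completed surveys vs one-per-day expectation over a closed period."""
    start, end = period
    if end < start:
        raise ValueError(f"empty period {start} .. {end}")
    expected = ((end - start).days + 1) * expected_per_day
    n = sum(1 for s in eods if start <= s.local_date <= end)
    return n, expected, _pct(n, expected)


def location_capture(
    reports: Sequence[SmokingReport],
) -> tuple[int, int, float, float, float]:
    """Share of reports with a location fix, plus accuracy mean/SD (located only)."""
    if not reports:
        raise ValueError("no reports")
    located = [r for r in reports if r.location is not None]
    mean, sd = _mean_sd([r.accuracy_m for r in located if r.accuracy_m is not None])
    return len(located), len(reports), _pct(len(located), len(reports)), mean, sd


@dataclass
class ResponseTimeStats:
    median_min: float
    iqr_min: float
    proportion_within: float
    n_within: int
    n_generated: int
    n_opened: int
    cdf: list[tuple[float, float]]


def response_time_stats(
    events: Sequence[TriggerEvent], threshold_min: float = 30.0
) -> ResponseTimeStats:
    """Notification-response latency summary.

    Median/IQR are computed over opened notifications only; the
    within-threshold proportion keeps every generated notification in the
    denominator (never-opened ones can never fall under the threshold).
    The CDF is over all generated notifications, right-censoring unopened
    ones at infinity, so it plateaus at the ever-opened proportion.
    """
    if not events:
        raise ValueError("no generated events")
    delays = sorted(
        e.elapsed_open_s / 60.0 for e in events if e.opened_at is not None
    )
    n_gen = len(events)
    n_within = sum(1 for d in delays if d <= threshold_min)
    if delays:
        median = float(np.median(delays))
        q1, q3 = np.percentile(delays, [25, 75])
        iqr = float(q3 - q1)
    else:
        median = iqr = float("nan")
    cdf = [(d, (i + 1) / n_gen) for i, d in enumerate(delays)]
    return ResponseTimeStats(
        median_min=median,
        iqr_min=iqr,
        proportion_within=n_within / n_gen,
        n_within=n_within,
        n_generated=n_gen,
        n_opened=len(delays),
        cdf=cdf,
    )


@dataclass
class EngagementRates:
    n_delivered: int
    n_rated: int
    percent_rated: float  # two decimals, the overall rate
    geofence_delivered: int
    geofence_entry: int
    geofence_dwell: int
    percent_entry: float
    percent_dwell: float
    geofence_rated: int
    percent_geofence_rated: float


def engagement_rates(events: Sequence[TriggerEvent]) -> EngagementRates:
    """Delivery and rating rates, overall and for the geofence-triggered subset.

    "Delivered" means the notification was opened and a message attached
    (``message_id`` present); zero-delivery inputs yield a zero-safe report.
    """
    delivered = [e for e in events if e.message_id is not None]
    rated = [e for e in delivered if e.rating is not None]
    geo = [e for e in delivered if e.type in (EventType.ENTRY, EventType.DWELL)]
    geo_entry = sum(1 for e in geo if e.type is EventType.ENTRY)
    geo_dwell = len(geo) - geo_entry
    geo_rated = sum(1 for e in geo if e.rating is not None)
    return EngagementRates(
        n_delivered=len(delivered),
        n_rated=len(rated),
        percent_rated=_pct(len(rated), len(delivered), 2),
        geofence_delivered=len(geo),
        geofence_entry=geo_entry,
        geofence_dwell=geo_dwell,
        percent_entry=_pct(geo_entry, len(geo)),
        percent_dwell=_pct(geo_dwell, len(geo)),
        geofence_rated=geo_rated,
        percent_geofence_rated=_pct(geo_rated, len(geo)),
    )


@dataclass
class UserData:
    """Everything one participant contributes to the feasibility report."""

    profile: UserProfile
    study_start: _dt.date
    reports: list[SmokingReport]
    eods: list[EoDSurvey]
    fences: list[Geofence]
    events: list[TriggerEvent]
    post_quit_days: int = 28


@dataclass
class FeasibilityReport:
    n_users: int
    reports_per_participant: tuple[float, float]
    reports_per_day: tuple[float, float]
    situation_counts: dict[str, tuple[int, float]]
    situation_total: int
    underreporting: tuple[int, int, float]
    location_capture: tuple[int, int, float]
    accuracy_m: tuple[float, float]
    geofences_per_participant: tuple[float, float]
    eod_compliance_pre: tuple[int, int, float]
    eod_compliance_post: tuple[int, int, float]
    messages_delivered: int
    messages_rated: tuple[int, int, float]
    engagement: EngagementRates
    response_time: Optional[ResponseTimeStats]

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and not math.isfinite(x):
                return None
            return x

        rt = self.response_time
        return {
            "n_users": self.n_users,
            "reports_per_participant": {
                "mean": clean(self.reports_per_participant[0]),
                "sd": clean(self.reports_per_participant[1]),
            },
            "reports_per_day": {
                "mean": clean(self.reports_per_day[0]),
                "sd": clean(self.reports_per_day[1]),
            },
            "situation_counts": {
                k: {"n": v[0], "percent": v[1]} for k, v in self.situation_counts.items()
            },
            "situation_total": self.situation_total,
            "underreporting": dict(
                zip(("days_under", "days_total", "percent"), self.underreporting)
            ),
            "location_capture": dict(
                zip(("n_with_location", "n_total", "percent"), self.location_capture)
            ),
            "accuracy_m": {"mean": clean(self.accuracy_m[0]), "sd": clean(self.accuracy_m[1])},
            "geofences_per_participant": {
                "mean": clean(self.geofences_per_participant[0]),
                "sd": clean(self.geofences_per_participant[1]),
            },
            "eod_compliance_pre": dict(
                zip(("n", "expected", "percent"), self.eod_compliance_pre)
            ),
            "eod_compliance_post": dict(
                zip(("n", "expected", "percent"), self.eod_compliance_post)
            ),
            "messages_delivered": self.messages_delivered,
            "messages_rated": dict(
                zip(("n", "n_delivered", "percent"), self.messages_rated)
            ),
            "geofence_messages": {
                "n_delivered": self.engagement.geofence_delivered,
                "n_entry": self.engagement.geofence_entry,
                "n_dwell": self.engagement.geofence_dwell,
                "percent_entry": self.engagement.percent_entry,
                "percent_dwell": self.engagement.percent_dwell,
                "percent_rated": self.engagement.percent_geofence_rated,
            },
            "response_time": None
            if rt is None
            else {
                "median_min": clean(rt.median_min),
                "iqr_min": clean(rt.iqr_min),
                "proportion_within_30min": rt.proportion_within,
                "n_within": rt.n_within,
                "n_generated": rt.n_generated,
                "n_opened": rt.n_opened,
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_table(self) -> str:
        d = self.to_dict()
        lines = [
            f"Feasibility outcomes (N={self.n_users})",
            f"Smoking reports per participant pre-quit, mean (SD)\t"
            f"{d['reports_per_participant']['mean']:.1f} ({d['reports_per_participant']['sd']:.1f})",
            f"Smoking reports per participant per day, mean (SD)\t"
            f"{d['reports_per_day']['mean']:.1f} ({d['reports_per_day']['sd']:.1f})",
            f"Reported situations (total N={self.situation_total}), n (%)",
        ]
        for name, (n, pct) in self.situation_counts.items():
            lines.append(f"  {name}\t{n} ({pct})")
        du, dt_, dp = self.underreporting
        lines.append(f"Under-reported days (EoD surveys N={dt_}), n (%)\t{du} ({dp})")
        lw, lt, lp = self.location_capture
        lines.append(f"Location capture (reports N={lt}), n (%)\t{lw} ({lp})")
        am, asd = self.accuracy_m
        lines.append(f"Location accuracy (m), mean (SD)\t{am:.1f} ({asd:.1f})")
        gm, gsd = self.geofences_per_participant
        lines.append(f"Geofences per participant, mean (SD)\t{gm:.1f} ({gsd:.1f})")
        for label, (n, exp, pct) in (
            ("pre-quit", self.eod_compliance_pre),
            ("post-quit", self.eod_compliance_post),
        ):
            lines.append(f"EoD compliance {label} (expected N={exp}), n (%)\t{n} ({pct})")
        lines.append(f"Support messages delivered, n\t{self.messages_delivered}")
        mr, md, mp = self.messages_rated
        lines.append(f"Messages rated (N={md}), n (%)\t{mr} ({mp})")
        e = self.engagement
        lines.append(
            f"Geofence messages delivered\t{e.geofence_delivered} "
            f"(entry {e.geofence_entry} [{e.percent_entry}%], "
            f"dwell {e.geofence_dwell} [{e.percent_dwell}%], "
            f"rated {e.geofence_rated} [{e.percent_geofence_rated}%])"
        )
        if self.response_time is not None and self.response_time.n_opened:
            rt = self.response_time
            lines.append(
                f"Notification response: median {rt.median_min:.1f} min "
                f"(IQR {rt.iqr_min:.1f}); within 30 min "
                f"{rt.n_within}/{rt.n_generated} "
                f"({_pct(rt.n_within, rt.n_generated)}%)"
            )
        return "\n".join(lines)


def feasibility_report(
    users: Sequence[UserData],
    bounds: CategoryBounds = DEFAULT_BOUNDS,
    tz_offset_min: int = 0,
) -> FeasibilityReport:
    """Assemble the full feasibility read-out for a cohort."""
    if not users:
        raise ValueError("empty cohort")
    pre_reports_all: list[SmokingReport] = []
    per_user_pre_counts: list[int] = []
    per_day_counts: list[int] = []
    fences_per_user: list[int] = []
    all_events: list[TriggerEvent] = []
    eod_pre_n = eod_pre_exp = eod_post_n = eod_post_exp = 0
    under_days = under_total = 0
    for u in users:
        quit = u.profile.quit_date
        if quit is None:
            raise ValueError(f"user {u.profile.user_id}: quit_date not set")
        pre_end = quit - _dt.timedelta(days=1)
        pre = [
            r
            for r in u.reports
            if local_date(r.timestamp, tz_offset_min) < quit
        ]
        pre_eods = [s for s in u.eods if s.local_date < quit]
        pre_reports_all.extend(pre)
        per_user_pre_counts.append(len(pre))
        day_counts: dict[_dt.date, int] = {}
        d = u.study_start
        while d <= pre_end:
            day_counts[d] = 0
            d += _dt.timedelta(days=1)
        for r in pre:
            day = local_date(r.timestamp, tz_offset_min)
            day_counts[day] = day_counts.get(day, 0) + 1
        per_day_counts.extend(day_counts.values())
        fences_per_user.append(len(u.fences))
        all_events.extend(u.events)
        uu, ut, _ = underreporting_days(pre, pre_eods, bounds, tz_offset_min)
        under_days += uu
        under_total += ut
        n, exp, _ = eod_compliance(pre_eods, (u.study_start, pre_end))
        eod_pre_n += n
        eod_pre_exp += exp
        post_end = quit + _dt.timedelta(days=u.post_quit_days - 1)
        post_eods = [s for s in u.eods if quit <= s.local_date <= post_end]
        n, exp, _ = eod_compliance(post_eods, (quit, post_end))
        eod_post_n += n
        eod_post_exp += exp

    situations = {s.value: 0 for s in Situation}
    for r in pre_reports_all:
        situations[r.situation.value] += 1
    sit_total = len(pre_reports_all)
    situation_counts = {
        name: (n, _pct(n, sit_total)) for name, n in situations.items()
    }
    all_reports = [r for u in users for r in u.reports]
    loc = location_capture(all_reports) if all_reports else (0, 0, 0.0, float("nan"), float("nan"))
    geo_events = [
        e for e in all_events if e.type in (EventType.ENTRY, EventType.DWELL)
    ]
    engagement = engagement_rates(all_events)
    rt = response_time_stats(geo_events) if geo_events else None
    return FeasibilityReport(
        n_users=len(users),
        reports_per_participant=_mean_sd(per_user_pre_counts),
        reports_per_day=_mean_sd(per_day_counts),
        situation_counts=situation_counts,
        situation_total=sit_total,
        underreporting=(under_days, under_total, _pct(under_days, under_total)),
        location_capture=loc[:3],
        accuracy_m=loc[3:],
        geofences_per_participant=_mean_sd(fences_per_user),
        eod_compliance_pre=(eod_pre_n, eod_pre_exp, _pct(eod_pre_n, eod_pre_exp)),
        eod_compliance_post=(eod_post_n, eod_post_exp, _pct(eod_post_n, eod_post_exp)),
        messages_delivered=engagement.n_delivered,
        messages_rated=(engagement.n_rated, engagement.n_delivered, engagement.percent_rated),
        engagement=engagement,
        response_time=rt,
    )


__all__ = [
    "CategoryBounds",
    "DEFAULT_BOUNDS",
    "underreporting_days",
    "eod_compliance",
    "location_capture",
    "ResponseTimeStats",
    "response_time_stats",
    "EngagementRates",
    "engagement_rates",
    "UserData",
    "FeasibilityReport",
    "feasibility_report",
]
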