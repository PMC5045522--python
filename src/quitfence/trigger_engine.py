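"""Geofence event state machine: ENTRY / DWELL / MORNING triggers.

A location trace is scanned against every fence independently. Presence in
a fence begins at the first contained sample and — by the continuity
assumption a 15-minute sampling cadence forces — persists until the first
non-contained sample, at whose timestamp exit occurs. Within a presence
interval:

* an ``ENTRY`` trigger fires ``entry_confirm_min`` (default 5) minutes
  after presence starts, provided containment persists through that
  instant;
* ``DWELL`` triggers fire every ``dwell_interval_h`` (default 3) hours
  after presence starts, again while containment persists.

Both clocks anchor to presence start and reset completely on exit.
Geofence events are only emitted during the quit window
(``COMMIT_TO_QUIT``). Morning notifications are scheduled daily during the
pre-quit and quit-window stages. Notifications never expire: an event can
be opened (and its message rated) arbitrarily late.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .geo import EARTH_RADIUS_M, Geofence, LocationSample, validate_trace
from .reporting import Stage, UserProfile, stage_of


class EventType(str, Enum):
    ENTRY = "ENTRY"
    DWELL = "DWELL"
    MORNING = "MORNING"
    POST_REPORT = "POST_REPORT"


@dataclass
class EngineConfig:
    entry_confirm_min: float = 5.0
    dwell_interval_h: float = 3.0
    sampling_interval_min: float = 15.0
    strict_containment: bool = True
    morning_time_local: _dt.time = _dt.time(8, 0)

    def __post_init__(self) -> None:
        for name in ("entry_confirm_min", "dwell_interval_h", "sampling_interval_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class TriggerEvent:
    event_id: str
    type: EventType
    generated_at: float
    geofence_id: Optional[str] = None
    opened_at: Optional[float] = None
    message_id: Optional[str] = None
    rating: Optional[int] = None

    def __post_init__(self) -> None:
        self.type = EventType(self.type)
        if self.type in (EventType.ENTRY, EventType.DWELL) and self.geofence_id is None:
            raise ValueError(f"{self.type.value} event requires a geofence_id")
        if self.opened_at is not None and self.opened_at < self.generated_at:
            raise ValueError("opened_at must be >= generated_at")
        if self.rating is not None:
            if self.message_id is None:
                raise ValueError("rating requires a delivered message")
            if not 1 <= self.rating <= 5:
                raise ValueError(f"rating {self.rating} outside 1..5")

    @property
    def elapsed_open_s(self) -> Optional[float]:
        return None if self.opened_at is None else self.opened_at - self.generated_at


def _contained_flags(trace: Sequence[LocationSample], fence: Geofence, strict: bool) -> np.ndarray:
    """Vectorised strict/lenient containment of every sample in one fence."""
    lat = np.radians(np.array([s.point.lat for s in trace]))
    lon = np.radians(np.array([s.point.lon for s in trace]))
    acc = np.array([s.accuracy_m for s in trace])
    clat, clon = np.radians(fence.center.lat), np.radians(fence.center.lon)
    h = (
        np.sin((lat - clat) / 2.0) ** 2
        + np.cos(clat) * np.cos(lat) * np.sin((lon - clon) / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    if strict:
        return d + acc <= fence.radius_m
    return d <= fence.radius_m


def detect_events(
    trace: Sequence[LocationSample],
    fences: Sequence[Geofence],
    config: Optional[EngineConfig] = None,
    profile: Optional[UserProfile] = None,
    tz_offset_min: int = 0,
) -> list[TriggerEvent]:
    """Emit ENTRY/DWELL events for a time-sorted trace against a fence set.

    Fences run independent state machines, so one sample may drive events
    in several overlapping fences. When ``profile`` is given, events whose
    generation instant falls outside the quit window are suppressed.
    Output is sorted by generation time (fence id breaking ties).
    """
    config = config or EngineConfig()
    trace = list(trace)
    validate_trace(trace)
    if not trace or not fences:
        return []
    entry_s = config.entry_confirm_min * 60.0
    dwell_s = config.dwell_interval_h * 3600.0
    times = np.array([s.timestamp for s in trace])
    t_last = times[-1]
    events: list[TriggerEvent] = []
    for fence in fences:
        inside = _contained_flags(trace, fence, config.strict_containment)
        i, n = 0, len(trace)
        while i < n:
            if not inside[i]:
                i += 1
                continue
            j = i  # run of contained samples [i, j]
            while j + 1 < n and inside[j + 1]:
                j += 1
            ps = times[i]
            if j + 1 < n:
                exit_t = times[j + 1]
                fire = lambda tau: tau < exit_t  # outside at the exit sample's instant
            else:
                fire = lambda tau: tau <= t_last  # presence known through trace end
            entry_t = ps + entry_s
            if fire(entry_t):
                events.append(
                    TriggerEvent("", EventType.ENTRY, entry_t, geofence_id=fence.id)
                )
            k = 1
            while fire(ps + k * dwell_s):
                tau = ps + k * dwell_s
                if tau != entry_t:  # entry takes precedence on a coincident tick
                    events.append(
                        TriggerEvent("", EventType.DWELL, tau, geofence_id=fence.id)
                    )
                k += 1
            i = j + 1
    if profile is not None:
        events = [
            e
            for e in events
            if stage_of(e.generated_at, profile, tz_offset_min) is Stage.COMMIT_TO_QUIT
        ]
    events.sort(key=lambda e: (e.generated_at, e.geofence_id or "", e.type.value))
    for idx, e in enumerate(events):
        e.event_id = f"ev-{idx:05d}"
    return events


def morning_events(
    date_range: tuple[_dt.date, _dt.date],
    profile: UserProfile,
    config: Optional[EngineConfig] = None,
    tz_offset_min: int = 0,
) -> list[TriggerEvent]:
    """One MORNING notification per local day at the configured clock time.

    Scheduled during the pre-quit and quit-window stages only; the range is
    a closed date interval and may be empty (end before start).
    """
    config = config or EngineConfig()
    start, end = date_range
    events: list[TriggerEvent] = []
    day = start
    while day <= end:
        local = _dt.datetime.combine(day, config.morning_time_local, tzinfo=_dt.timezone.utc)
        ts = local.timestamp() - tz_offset_min * 60
        if stage_of(ts, profile, tz_offset_min) is not Stage.MAINTAIN_THE_CHANGE:
            events.append(TriggerEvent(f"morning-{day.isoformat()}", EventType.MORNING, ts))
        day += _dt.timedelta(days=1)
    return events


def record_interaction(
    event: TriggerEvent, opened_at: float, rating: Optional[int] = None
) -> TriggerEvent:
    """Attach an open time (and optional 1-5 star rating) to an event."""
    if opened_at < event.generated_at:
        raise ValueError(
            f"opened_at {opened_at} precedes generation at {event.generated_at}"
        )
    return replace(event, opened_at=opened_at, rating=rating)


__all__ = [
    "EventType",
    "EngineConfig",
    "TriggerEvent",
    "detect_events",
    "morning_events",
    "record_interaction",
]
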