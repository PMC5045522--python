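"""Tailored support-message selection and data-driven feedback.

Messages are tagged by stage, trigger type, and optionally by situation
(Home/Working/Socializing/Other) and stress band; they may also require
specific profile answers (``profile_keys``). Selection filters the pool by
trigger and stage (never relaxed), then by the user's hard profile keys,
then — for geofence triggers — by the fence's modal situation and mean
stress band. If no candidate survives, the situational filters relax in
order: stress band first, then situation. Already-delivered messages are
avoided until the candidate set is exhausted, at which point the rotation
restarts. The final pick among candidates is uniform under a caller seed,
so selection is reproducible.

Stress bands on the 1-5 scale: LOW < 2.5 <= MODERATE <= 3.5 < HIGH. The
cut-points are configuration, chosen so MODERATE straddles the scale
midpoint; the band vocabulary mirrors "moderate-to-high stress" style
content tagging.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .geo import Geofence
from .reporting import Situation, SmokingReport, Stage, UserProfile
from .trigger_engine import EventType, TriggerEvent


class StressBand(str, Enum):
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


class TriggerTag(str, Enum):
    GEOFENCE = "GEOFENCE"
    MORNING = "MORNING"
    POST_REPORT = "POST_REPORT"
    FEEDBACK = "FEEDBACK"


STRESS_BAND_CUTS = (2.5, 3.5)

# Tie-break priority when situations are equally frequent.
_SITUATION_PRIORITY = (
    Situation.HOME,
    Situation.WORKING,
    Situation.SOCIALIZING,
    Situation.OTHER,
)

_EVENT_TO_TRIGGER = {
    EventType.ENTRY: TriggerTag.GEOFENCE,
    EventType.DWELL: TriggerTag.GEOFENCE,
    EventType.MORNING: TriggerTag.MORNING,
    EventType.POST_REPORT: TriggerTag.POST_REPORT,
}


class NoContentError(LookupError):
    """No message in the pool matches the trigger/stage even after relaxation."""


@dataclass(frozen=True)
class SupportMessage:
    message_id: str
    text: str
    stage_tag: Stage
    trigger_tag: TriggerTag
    situation_tag: Optional[Situation] = None
    stress_band_tag: Optional[StressBand] = None
    profile_keys: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("message text must be non-empty")

    def matches_profile(self, profile: UserProfile) -> bool:
        keys = profile.as_tailoring_keys()
        return all(keys.get(k) == v for k, v in self.profile_keys)


@dataclass
class GeofenceContext:
    """Aggregate of the self-reports made at one learned smoking location."""

    geofence_id: str
    n_reports: int
    mean_stress: float
    mean_mood: float
    mean_urge: float
    modal_situation: Situation
    situation_proportions: dict[Situation, float]
    company_smoking_proportion: float


def stress_band(mean_stress: float) -> StressBand:
    """Band a mean stress rating on the 1-5 scale."""
    if not 1.0 <= mean_stress <= 5.0:
        raise ValueError(f"mean stress {mean_stress} outside [1, 5]")
    lo, hi = STRESS_BAND_CUTS
    if mean_stress < lo:
        return StressBand.LOW
    if mean_stress <= hi:
        return StressBand.MODERATE
    return StressBand.HIGH


def context_profile(fence: Geofence, reports: Sequence[SmokingReport]) -> GeofenceContext:
    """Summarise the member reports of a fence into its tailoring context."""
    members = [r for r in reports if r.report_id in fence.member_report_ids]
    if not members:
        raise ValueError(f"geofence {fence.id} has no member reports in the log")
    n = len(members)
    situations = Counter(r.situation for r in members)
    top = max(situations.values())
    modal = next(s for s in _SITUATION_PRIORITY if situations.get(s) == top)
    smoking_present = sum(1 for r in members if r.others_smoking)
    return GeofenceContext(
        geofence_id=fence.id,
        n_reports=n,
        mean_stress=sum(r.stress for r in members) / n,
        mean_mood=sum(r.mood for r in members) / n,
        mean_urge=sum(r.urge_strength for r in members) / n,
        modal_situation=modal,
        situation_proportions={s: c / n for s, c in situations.items()},
        company_smoking_proportion=smoking_present / n,
    )


def _stage_of_event(event: TriggerEvent, profile: UserProfile, tz_offset_min: int) -> Stage:
    from .reporting import stage_of

    return stage_of(event.generated_at, profile, tz_offset_min)


def select_message(
    pool: Sequence[SupportMessage],
    event: TriggerEvent,
    context: Optional[GeofenceContext],
    profile: UserProfile,
    history: Iterable[str],
    seed: int,
    tz_offset_min: int = 0,
) -> SupportMessage:
    """Pick one message for an event; pure in all arguments.

    Raises :class:`NoContentError` when the pool holds nothing for the
    event's trigger/stage combination (those two tags never relax).
    """
    if not pool:
        raise NoContentError("empty message pool")
    trigger = _EVENT_TO_TRIGGER[event.type]
    stage = _stage_of_event(event, profile, tz_offset_min)
    base = [
        m
        for m in pool
        if m.trigger_tag is trigger and m.stage_tag is stage and m.matches_profile(profile)
    ]
    if not base:
        raise NoContentError(f"no message for trigger={trigger.value} stage={stage.value}")

    situation = context.modal_situation if context else None
    band = stress_band(context.mean_stress) if context else None

    def filtered(use_situation: bool, use_band: bool) -> list[SupportMessage]:
        out = base
        if use_situation and situation is not None:
            out = [m for m in out if m.situation_tag in (None, situation)]
        if use_band and band is not None:
            out = [m for m in out if m.stress_band_tag in (None, band)]
        return out

    # Relaxation ladder: full match, then drop the stress band, then the situation.
    candidates: list[SupportMessage] = []
    for use_situation, use_band in ((True, True), (True, False), (False, False)):
        candidates = filtered(use_situation, use_band)
        if candidates:
            break
    history_set = set(history)
    fresh = [m for m in candidates if m.message_id not in history_set]
    if not fresh:  # rotation exhausted for this tag combination; restart it
        fresh = candidates
    rng = np.random.default_rng(seed)
    return fresh[int(rng.integers(len(fresh)))]


class MessageSelector:
    """Stateful wrapper that tracks delivery history across selections.

    History is kept per (trigger, stage) combination; when a combination's
    rotation is exhausted (a previously delivered message comes back), only
    that combination's history restarts.
    """

    def __init__(self, pool: Sequence[SupportMessage], seed: int, tz_offset_min: int = 0):
        self.pool = list(pool)
        self.tz_offset_min = tz_offset_min
        self._rng = np.random.default_rng(seed)
        self._history: dict[tuple[TriggerTag, Stage], set[str]] = {}

    def select(
        self,
        event: TriggerEvent,
        context: Optional[GeofenceContext],
        profile: UserProfile,
    ) -> SupportMessage:
        key = (
            _EVENT_TO_TRIGGER[event.type],
            _stage_of_event(event, profile, self.tz_offset_min),
        )
        seen = self._history.setdefault(key, set())
        msg = select_message(
            self.pool,
            event,
            context,
            profile,
            seen,
            seed=int(self._rng.integers(2**31)),
            tz_offset_min=self.tz_offset_min,
        )
        if msg.message_id in seen:
            seen.clear()
        seen.add(msg.message_id)
        return msg


_SITUATION_PHRASE = {
    Situation.HOME: "at home",
    Situation.WORKING: "working",
    Situation.SOCIALIZING: "socializing",
    Situation.OTHER: "in other situations",
}

FEEDBACK_TEMPLATE = (
    "Did you know? Based on {n} reports, {percent}% of the times you smoke you are {phrase}."
)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from the floor (the convention percent text uses)."""
    factor = 10**decimals
    return math.floor(x * factor + 0.5) / factor


def feedback_message(
    reports: Sequence[SmokingReport], situation: Situation
) -> tuple[str, int, float]:
    """Render the situation-share feedback line from the report log.

    Returns ``(text, n_reports, raw_percent)``; the text shows the percent
    rounded half-up to an integer.
    """
    if not reports:
        raise ValueError("no reports to summarise")
    n = len(reports)
    matching = sum(1 for r in reports if r.situation is situation)
    percent = 100.0 * matching / n
    text = FEEDBACK_TEMPLATE.format(
        n=n, percent=int(round_half_up(percent)), phrase=_SITUATION_PHRASE[situation]
    )
    return text, n, percent


__all__ = [
    "StressBand",
    "TriggerTag",
    "STRESS_BAND_CUTS",
    "NoContentError",
    "SupportMessage",
    "GeofenceContext",
    "stress_band",
    "context_profile",
    "select_message",
    "MessageSelector",
    "feedback_message",
    "round_half_up",
    "FEEDBACK_TEMPLATE",
]
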