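"""Readers and writers for the plain-text interchange formats.

Traces are CSV (``timestamp,lat,lon,accuracy_m``), record streams
(reports, diaries, events) are JSONL, geofences are GeoJSON Point features
with the fence parameters in ``properties``, profiles and scenario
configuration are YAML. Timestamps in files are ISO-8601 UTC; epoch
seconds are also accepted on input. Every writer/reader pair is a
round-trip identity on valid data.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .geo import FenceOrigin, Geofence, GeoPoint, LocationSample
from .reporting import (
    Company,
    EoDSurvey,
    Situation,
    SmokingReport,
    Stage,
    UserProfile,
)
from .trigger_engine import EventType, TriggerEvent


class FormatError(ValueError):
    """A file failed to parse; the message carries file/line context."""


def parse_timestamp(value: str | float | int) -> float:
    """Accept epoch seconds or ISO-8601; return UTC epoch seconds."""
    if isinstance(value, (int, float)):
        return float(value)
    text = value.strip()
    try:
        return float(text)
    except ValueError:
        pass
    try:
        dt = _dt.datetime.fromisoformat(text.replace("Z", "+00:00"))
    except ValueError as exc:
        raise FormatError(f"unparseable timestamp {value!r}") from exc
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=_dt.timezone.utc)
    return dt.timestamp()


def format_timestamp(ts: float) -> str:
    dt = _dt.datetime.fromtimestamp(ts, tz=_dt.timezone.utc)
    return dt.isoformat().replace("+00:00", "Z")


# --- traces -----------------------------------------------------------------

TRACE_HEADER = ["timestamp", "lat", "lon", "accuracy_m"]


def write_trace(trace: Sequence[LocationSample], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(TRACE_HEADER) + "\n")
        for s in trace:
            fh.write(
                f"{format_timestamp(s.timestamp)},{s.point.lat:.7f},"
                f"{s.point.lon:.7f},{s.accuracy_m:.2f}\n"
            )


def read_trace(path: str | Path, strict_sorted: bool = True) -> list[LocationSample]:
    samples: list[LocationSample] = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header != TRACE_HEADER:
            raise FormatError(f"{path}: expected header {TRACE_HEADER}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                sample = LocationSample(
                    parse_timestamp(parts[0]),
                    GeoPoint(float(parts[1]), float(parts[2])),
                    float(parts[3]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            samples.append(sample)
    if strict_sorted:
        for i in range(1, len(samples)):
            if samples[i].timestamp <= samples[i - 1].timestamp:
                raise FormatError(
                    f"{path}: timestamps not strictly increasing at row {i + 2}"
                )
    return samples


# --- geofences --------------------------------------------------------------


def write_geofences(fences: Sequence[Geofence], path: str | Path) -> None:
    features = []
    for f in fences:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [f.center.lon, f.center.lat]},
                "properties": {
                    "id": f.id,
                    "radius_m": f.radius_m,
                    "origin": f.origin.value,
                    "member_report_ids": sorted(f.member_report_ids),
                    "created_at": format_timestamp(f.created_at),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=2)


def read_geofences(path: str | Path) -> list[Geofence]:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: not a GeoJSON FeatureCollection")
    fences = []
    for i, feature in enumerate(data.get("features", [])):
        geom = feature.get("geometry") or {}
        if geom.get("type") != "Point":
            raise FormatError(f"{path}: feature {i} geometry is not a Point")
        props = feature.get("properties") or {}
        if "radius_m" not in props:
            raise FormatError(f"{path}: feature {i} missing radius_m property")
        lon, lat = geom["coordinates"]
        fences.append(
            Geofence(
                id=str(props.get("id", f"gf-{i:03d}")),
                center=GeoPoint(lat, lon),
                radius_m=float(props["radius_m"]),
                member_report_ids=frozenset(props.get("member_report_ids", [])),
                created_at=parse_timestamp(props.get("created_at", 0.0)),
                origin=FenceOrigin(props.get("origin", "PRE_QUIT_CLUSTER")),
            )
        )
    return fences


# --- reports / diaries / events (JSONL) -------------------------------------


def write_reports(reports: Sequence[SmokingReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reports:
            rec = {
                "report_id": r.report_id,
                "timestamp": format_timestamp(r.timestamp),
                "mood": r.mood,
                "stress": r.stress,
                "urge_strength": r.urge_strength,
                "situation": r.situation.value,
                "company": r.company.value,
                "others_smoking": r.others_smoking,
                "stage_at_report": r.stage_at_report.value,
            }
            if r.location is not None:
                rec["lat"] = r.location.lat
                rec["lon"] = r.location.lon
                rec["accuracy_m"] = r.accuracy_m
            fh.write(json.dumps(rec) + "\n")


def read_reports(path: str | Path) -> list[SmokingReport]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                location = None
                accuracy = None
                if rec.get("lat") is not None:
                    location = GeoPoint(rec["lat"], rec["lon"])
                    accuracy = float(rec["accuracy_m"])
                out.append(
                    SmokingReport(
                        report_id=rec["report_id"],
                        timestamp=parse_timestamp(rec["timestamp"]),
                        mood=rec["mood"],
                        stress=rec["stress"],
                        urge_strength=rec["urge_strength"],
                        situation=Situation(rec["situation"]),
                        company=Company(rec["company"]),
                        others_smoking=rec.get("others_smoking"),
                        location=location,
                        accuracy_m=accuracy,
                        stage_at_report=Stage(rec.get("stage_at_report", "PREPARE_AND_LEARN")),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_eods(eods: Sequence[EoDSurvey], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in eods:
            fh.write(
                json.dumps(
                    {
                        "user_id": s.user_id,
                        "local_date": s.local_date.isoformat(),
                        "cigarettes_category": s.cigarettes_category,
                        "urge_strength": s.urge_strength,
                        "urge_frequency": s.urge_frequency,
                        "abstinence_self_efficacy": s.abstinence_self_efficacy,
                    }
                )
                + "\n"
            )


def read_eods(path: str | Path) -> list[EoDSurvey]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                out.append(
                    EoDSurvey(
                        user_id=rec["user_id"],
                        local_date=_dt.date.fromisoformat(rec["local_date"]),
                        cigarettes_category=rec["cigarettes_category"],
                        urge_strength=rec["urge_strength"],
                        urge_frequency=rec["urge_frequency"],
                        abstinence_self_efficacy=rec["abstinence_self_efficacy"],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_events(events: Sequence[TriggerEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in events:
            rec = {
                "event_id": e.event_id,
                "type": e.type.value,
                "generated_at": format_timestamp(e.generated_at),
                "geofence_id": e.geofence_id,
                "opened_at": None if e.opened_at is None else format_timestamp(e.opened_at),
                "message_id": e.message_id,
                "rating": e.rating,
            }
            fh.write(json.dumps(rec) + "\n")


def read_events(path: str | Path) -> list[TriggerEvent]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                out.append(
                    TriggerEvent(
                        event_id=rec["event_id"],
                        type=EventType(rec["type"]),
                        generated_at=parse_timestamp(rec["generated_at"]),
                        geofence_id=rec.get("geofence_id"),
                        opened_at=(
                            None
                            if rec.get("opened_at") is None
                            else parse_timestamp(rec["opened_at"])
                        ),
                        message_id=rec.get("message_id"),
                        rating=rec.get("rating"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


# --- profiles ---------------------------------------------------------------


def write_profile(profile: UserProfile, path: str | Path) -> None:
    data = {
        "user_id": profile.user_id,
        "quit_date": profile.quit_date.isoformat() if profile.quit_date else None,
        "gender": profile.gender,
        "age_band": profile.age_band,
        "cigarettes_per_day_band": profile.cigarettes_per_day_band,
        "first_cigarette_within_30min": profile.first_cigarette_within_30min,
        "lives_with_smokers": profile.lives_with_smokers,
        "plans_ecigarette": profile.plans_ecigarette,
        "extra_items": dict(profile.extra_items),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_profile(path: str | Path) -> UserProfile:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    quit = data.get("quit_date")
    return UserProfile(
        user_id=data["user_id"],
        quit_date=_dt.date.fromisoformat(quit) if quit else None,
        gender=data.get("gender"),
        age_band=data.get("age_band"),
        cigarettes_per_day_band=data.get("cigarettes_per_day_band"),
        first_cigarette_within_30min=data.get("first_cigarette_within_30min"),
        lives_with_smokers=data.get("lives_with_smokers"),
        plans_ecigarette=data.get("plans_ecigarette"),
        extra_items=data.get("extra_items") or {},
    )


__all__ = [
    "FormatError",
    "parse_timestamp",
    "format_timestamp",
    "read_trace",
    "write_trace",
    "read_geofences",
    "write_geofences",
    "read_reports",
    "write_reports",
    "read_eods",
    "write_eods",
    "read_events",
    "write_events",
    "read_profile",
    "write_profile",
]
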