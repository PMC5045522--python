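"""Coordinate arithmetic and circular-geofence containment.

Coordinates are WGS84 decimal degrees; distances are great-circle
(haversine) on a sphere of radius 6,371,000 m, which is accurate to well
under a metre at the sub-kilometre scales a geofence engine cares about —
far below the ~30 m accuracy radius typical of phone location fixes.

Containment supports two semantics:

* **strict** (default): the reported accuracy circle must lie entirely
  inside the fence, i.e. ``distance(center, point) + accuracy <= radius``.
  This models platforms that suppress geofence events when the location
  estimate is not fully inside the perimeter — the known failure mode when
  GPS accuracy is poor.
* **lenient**: only the point estimate matters (``distance <= radius``),
  useful for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

EARTH_RADIUS_M = 6_371_000.0


class FenceOrigin(str, Enum):
    """How a geofence came to exist."""

    PRE_QUIT_CLUSTER = "PRE_QUIT_CLUSTER"
    LAPSE = "LAPSE"


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 coordinate in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValueError(f"non-finite coordinate ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class LocationSample:
    """A timestamped location fix with a 68%-confidence accuracy radius.

    ``timestamp`` is UTC epoch seconds. ``accuracy_m`` is the radius within
    which the true position lies with 68% probability, as reported by the
    device location service.
    """

    timestamp: float
    point: GeoPoint
    accuracy_m: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.accuracy_m) or self.accuracy_m < 0:
            raise ValueError(f"accuracy_m must be >= 0, got {self.accuracy_m}")


@dataclass
class Geofence:
    """A circular virtual perimeter around a learned smoking location."""

    id: str
    center: GeoPoint
    radius_m: float
    member_report_ids: frozenset[str] = field(default_factory=frozenset)
    created_at: float = 0.0
    origin: FenceOrigin = FenceOrigin.PRE_QUIT_CLUSTER

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError(f"radius_m must be > 0, got {self.radius_m}")
        self.member_report_ids = frozenset(self.member_report_ids)
        self.origin = FenceOrigin(self.origin)


def haversine_m(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, in metres."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon - a.lon)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def contains(fence: Geofence, sample: LocationSample, strict: bool = True) -> bool:
    """Whether a location sample counts as inside the geofence.

    Strict mode requires the whole accuracy circle inside the fence;
    lenient mode tests only the point estimate.
    """
    d = haversine_m(fence.center, sample.point)
    if strict:
        return d + sample.accuracy_m <= fence.radius_m
    return d <= fence.radius_m


def destination(origin: GeoPoint, bearing_deg: float, distance_m: float) -> GeoPoint:
    """Point reached travelling ``distance_m`` from ``origin`` along ``bearing_deg``.

    Spherical direct geodesic; used by the simulator to lay out anchors and
    positional noise in metres rather than degrees.
    """
    delta = distance_m / EARTH_RADIUS_M
    theta = math.radians(bearing_deg)
    phi1 = math.radians(origin.lat)
    lam1 = math.radians(origin.lon)
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    )
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    lon = math.degrees(lam2)
    if lon > 180.0:
        lon -= 360.0
    elif lon < -180.0:
        lon += 360.0
    return GeoPoint(math.degrees(phi2), lon)


def validate_trace(trace: list[LocationSample]) -> None:
    """Raise ``ValueError`` unless timestamps are strictly increasing."""
    for i in range(1, len(trace)):
        if trace[i].timestamp <= trace[i - 1].timestamp:
            raise ValueError(
                f"trace timestamps not strictly increasing at index {i}: "
                f"{trace[i - 1].timestamp} -> {trace[i].timestamp}"
            )


__all__ = [
    "EARTH_RADIUS_M",
    "FenceOrigin",
    "GeoPoint",
    "LocationSample",
    "Geofence",
    "haversine_m",
    "contains",
    "destination",
    "validate_trace",
]
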