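"""Learn geofences from located smoking reports.

Reports are assigned incrementally (in arrival order) to the nearest
cluster whose running centroid is within the proximity threshold; a report
matching no cluster seeds a new one. A cluster whose membership reaches the
activation threshold (default 5 — i.e. "more than four reports in the same
proximity") becomes a geofence: its centre freezes at the centroid at the
moment of activation and never moves again, mirroring a platform whose
registered geofences are static. Later reports landing inside a frozen
cluster still join its membership — that context feeds message tailoring —
but do not re-centre it.

The second-generation refinements are plain configuration: a lower
activation threshold (``v2_threshold``) and fences created around lapses
reported during the quit attempt (``lapse_geofences``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .geo import FenceOrigin, Geofence, GeoPoint, LocationSample, contains, haversine_m
from .reporting import SmokingReport, Stage

logger = logging.getLogger(__name__)


@dataclass
class BuilderConfig:
    radius_m: float = 100.0
    activation_threshold: int = 5
    proximity_threshold_m: Optional[float] = None  # defaults to radius_m
    lapse_geofences: bool = False
    v2_threshold: Optional[int] = None

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError("radius_m must be > 0")
        if self.activation_threshold < 1:
            raise ValueError("activation_threshold must be >= 1")
        if self.proximity_threshold_m is None:
            self.proximity_threshold_m = self.radius_m
        if self.proximity_threshold_m <= 0:
            raise ValueError("proximity_threshold_m must be > 0")
        if self.v2_threshold is not None and not 1 <= self.v2_threshold:
            raise ValueError("v2_threshold must be >= 1")

    @property
    def effective_threshold(self) -> int:
        return self.v2_threshold if self.v2_threshold is not None else self.activation_threshold


@dataclass
class ClusterState:
    """Running state of one candidate smoking location."""

    centroid: GeoPoint
    member_report_ids: list[str] = field(default_factory=list)
    activated: bool = False
    frozen_center: Optional[GeoPoint] = None
    activated_at: Optional[float] = None
    _lat_sum: float = 0.0
    _lon_sum: float = 0.0

    @classmethod
    def seed(cls, report: SmokingReport) -> "ClusterState":
        assert report.location is not None
        c = cls(centroid=report.location)
        c._lat_sum = report.location.lat
        c._lon_sum = report.location.lon
        c.member_report_ids.append(report.report_id)
        return c

    def add(self, report: SmokingReport) -> None:
        assert report.location is not None
        self.member_report_ids.append(report.report_id)
        self._lat_sum += report.location.lat
        self._lon_sum += report.location.lon
        if not self.activated:
            n = len(self.member_report_ids)
            self.centroid = GeoPoint(self._lat_sum / n, self._lon_sum / n)

    @property
    def center(self) -> GeoPoint:
        return self.frozen_center if self.activated else self.centroid


def assign_report(
    report: SmokingReport, clusters: list[ClusterState], config: BuilderConfig
) -> list[ClusterState]:
    """Assign one located report to the cluster list (mutates and returns it).

    Nearest cluster within the proximity threshold wins; ties break to the
    earliest-created cluster so the procedure is deterministic. Reports
    without a location fix are skipped with a warning (they mirror the
    location-capture failures the app tolerates).
    """
    if report.location is None:
        logger.warning("report %s has no location fix; skipping", report.report_id)
        return clusters
    best: Optional[ClusterState] = None
    best_d = float("inf")
    for cluster in clusters:  # earliest-created first; strict < keeps ties on the first
        d = haversine_m(cluster.center, report.location)
        if d <= config.proximity_threshold_m and d < best_d:
            best, best_d = cluster, d
    if best is None:
        best = ClusterState.seed(report)
        clusters.append(best)
    else:
        best.add(report)
    if not best.activated and len(best.member_report_ids) >= config.effective_threshold:
        best.activated = True
        best.frozen_center = best.centroid
        best.activated_at = report.timestamp
    return clusters


def build_geofences(
    reports: Sequence[SmokingReport], config: Optional[BuilderConfig] = None
) -> list[Geofence]:
    """Run incremental clustering over time-ordered reports; emit active fences."""
    config = config or BuilderConfig()
    clusters: list[ClusterState] = []
    for report in reports:
        assign_report(report, clusters, config)
    fences = []
    for i, cluster in enumerate(c for c in clusters if c.activated):
        assert cluster.frozen_center is not None and cluster.activated_at is not None
        fences.append(
            Geofence(
                id=f"gf-{i:03d}",
                center=cluster.frozen_center,
                radius_m=config.radius_m,
                member_report_ids=frozenset(cluster.member_report_ids),
                created_at=cluster.activated_at,
                origin=FenceOrigin.PRE_QUIT_CLUSTER,
            )
        )
    return fences


def add_lapse_geofence(
    report: SmokingReport, geofences: list[Geofence], config: BuilderConfig
) -> list[Geofence]:
    """Version-2 behaviour: fence any located lapse at a novel location.

    No-op unless ``config.lapse_geofences`` is enabled; a lapse already
    inside an existing fence (lenient containment on the point estimate)
    adds nothing.
    """
    if not config.lapse_geofences:
        return geofences
    if report.location is None or report.stage_at_report is not Stage.COMMIT_TO_QUIT:
        return geofences
    sample = LocationSample(report.timestamp, report.location, report.accuracy_m or 0.0)
    if any(contains(f, sample, strict=False) for f in geofences):
        return geofences
    geofences.append(
        Geofence(
            id=f"lapse-{report.report_id}",
            center=report.location,
            radius_m=config.radius_m,
            member_report_ids=frozenset({report.report_id}),
            created_at=report.timestamp,
            origin=FenceOrigin.LAPSE,
        )
    )
    return geofences


__all__ = ["BuilderConfig", "ClusterState", "assign_report", "build_geofences", "add_lapse_geofence"]
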