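"""End-to-end pipeline: simulate -> learn fences -> trigger -> metrics."""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .corpus import placeholder_corpus
from .geofence_builder import BuilderConfig, build_geofences
from .metrics import FeasibilityReport, UserData, feasibility_report
from .reporting import Stage
from .simulator import Cohort, SimScenario, UserSim, simulate_cohort, simulate_interactions
from .tailoring import MessageSelector, context_profile
from .trigger_engine import EngineConfig, detect_events, morning_events
from . import io as qio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scenario: SimScenario = field(default_factory=SimScenario)
    builder: BuilderConfig = field(default_factory=BuilderConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    out_dir: Optional[Path] = None

    @property
    def tz_offset_min(self) -> int:
        return self.scenario.tz_offset_min


def process_user(sim: UserSim, config: PipelineConfig) -> UserData:
    """Run the learning/triggering/interaction stages for one simulated user."""
    scenario = config.scenario
    tz = scenario.tz_offset_min
    pre_located = [
        r
        for r in sorted(sim.reports, key=lambda r: r.timestamp)
        if r.stage_at_report is Stage.PREPARE_AND_LEARN and r.location is not None
    ]
    fences = build_geofences(pre_located, config.builder)
    geo_events = detect_events(sim.trace, fences, config.engine, sim.profile, tz)
    study_end = scenario.study_start + _dt.timedelta(days=scenario.total_days - 1)
    mornings = morning_events((scenario.study_start, study_end), sim.profile, config.engine, tz)
    contexts = {f.id: context_profile(f, sim.reports) for f in fences}
    user_seed = int.from_bytes(sim.profile.user_id.encode(), "little") % (2**31)
    selector = MessageSelector(placeholder_corpus(), seed=user_seed ^ scenario.seed, tz_offset_min=tz)

    def select(event):
        ctx = contexts.get(event.geofence_id) if event.geofence_id else None
        return selector.select(event, ctx, sim.profile).message_id

    events = simulate_interactions(
        geo_events + mornings, scenario, seed=user_seed ^ scenario.seed, select=select
    )
    return UserData(
        profile=sim.profile,
        study_start=scenario.study_start,
        reports=sim.reports,
        eods=sim.eods,
        fences=fences,
        events=events,
        post_quit_days=scenario.post_quit_days,
    )


def run_pipeline(config: PipelineConfig) -> FeasibilityReport:
    """Simulate a cohort, run every stage, and assemble the feasibility report.

    When ``config.out_dir`` is set, the full artifact tree (per-user traces,
    reports, diaries, fences, events, plus report.json and a text table) is
    written there.
    """
    scenario = config.scenario
    logger.info("simulating cohort: %d users, seed %d", scenario.n_users, scenario.seed)
    cohort = simulate_cohort(scenario)
    users = []
    for sim in cohort.users:
        users.append(process_user(sim, config))
    logger.info(
        "processed %d users: %d fences, %d events",
        len(users),
        sum(len(u.fences) for u in users),
        sum(len(u.events) for u in users),
    )
    report = feasibility_report(users, tz_offset_min=scenario.tz_offset_min)
    if config.out_dir is not None:
        _write_artifacts(cohort, users, report, Path(config.out_dir))
    return report


def _write_artifacts(
    cohort: Cohort, users: list[UserData], report: FeasibilityReport, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    import json

    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=2))
    for sim, data in zip(cohort.users, users):
        udir = out / sim.profile.user_id
        udir.mkdir(exist_ok=True)
        qio.write_profile(sim.profile, udir / "profile.yaml")
        qio.write_trace(sim.trace, udir / "trace.csv")
        qio.write_reports(sim.reports, udir / "reports.jsonl")
        qio.write_eods(sim.eods, udir / "eods.jsonl")
        qio.write_geofences(data.fences, udir / "fences.geojson")
        qio.write_events(data.events, udir / "events.jsonl")
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_table())
    logger.info("artifacts written to %s", out)


__all__ = ["PipelineConfig", "process_user", "run_pipeline"]
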