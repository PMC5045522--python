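# quitfence

A headless engine for **location-triggered, just-in-time smoking-cessation
support**, plus the synthetic smoker/mobility simulator and feasibility
metrics needed to evaluate it end to end — no device, server, or real
participant data required.

Smoking is strongly cue-driven: cravings peak in the places where a person
habitually smoked. `quitfence` implements the full loop a context-aware
cessation app runs:

1. **Learn** — before the quit date, the user logs each cigarette in real
   time with a 5-item context assessment (mood, stress, urge strength
   0–5, situation, company). Located reports are clustered; more than four
   reports in the same proximity create a circular **geofence**
   (radius 100 m) around that smoking location.
2. **Trigger** — during the 28-day quit window, background location
   samples (every 15 min) are matched against the fences with *strict*
   containment (`distance + accuracy_radius ≤ fence_radius`, so a poor
   fix suppresses events). Confirmed presence for 5 minutes raises an
   ENTRY notification; each further 3 hours of dwelling raises a DWELL
   notification; mornings get a scheduled message.
3. **Tailor** — messages are selected by stage, trigger type, the fence's
   aggregated context (modal situation, mean-stress band) and the user's
   demographics/smoking survey, with deterministic seeded choice and
   no-repeat rotation; data-driven feedback lines like *"Based on 12
   reports, 25% of the times you smoke you are working."* are rendered
   from the log.
4. **Measure** — compliance, under-reporting against the end-of-day diary,
   location-capture quality, geofence yield, delivery/rating rates, and
   the notification response-time distribution, assembled into a
   feasibility report.

It is aimed at mHealth/JITAI researchers who want to prototype trigger
logic and measurement pipelines against controllable synthetic cohorts.

## Worked example

```python
from collections import Counter
from quitfence import (SimScenario, simulate_user, build_geofences,
                       detect_events, context_profile, stress_band,
                       feedback_message, Situation, Stage)

scenario = SimScenario(seed=42)            # 15-user defaults; we take user 0
sim = simulate_user(scenario, 0)

pre = sorted((r for r in sim.reports
              if r.stage_at_report is Stage.PREPARE_AND_LEARN
              and r.location is not None), key=lambda r: r.timestamp)
fences = build_geofences(pre)
for f in fences:
    ctx = context_profile(f, sim.reports)
    print(f"{f.id}: {len(f.member_report_ids)} reports, "
          f"modal={ctx.modal_situation.value}, mean stress={ctx.mean_stress:.2f} "
          f"({stress_band(ctx.mean_stress).value})")

events = detect_events(sim.trace, fences, profile=sim.profile)
print("events:", Counter(e.type.value for e in events))
print(feedback_message(pre, Situation.WORKING)[0])
```

Output:

```
gf-000: 28 reports, modal=Home, mean stress=3.25 (MODERATE)
gf-001: 15 reports, modal=Working, mean stress=3.80 (HIGH)
events: Counter({'ENTRY': 293, 'DWELL': 74})
Did you know? Based on 51 reports, 29% of the times you smoke you are working.
```

The user's 51 located pre-quit reports resolved into two fences — a home
location with moderate reported stress and a work location with high
stress — and replaying the 48-day background trace against them during the
quit window produced 293 entry and 74 dwell triggers, each of which would
carry a message tailored to that fence's context.

The same pipeline is available from the shell:

```bash
quitfence simulate --seed 42 --out fixtures/
quitfence build-geofences --reports fixtures/user-000/reports.jsonl \
    --out fixtures/user-000/fences.geojson
quitfence run-engine --trace fixtures/user-000/trace.csv \
    --fences fixtures/user-000/fences.geojson \
    --profile fixtures/user-000/profile.yaml \
    --out fixtures/user-000/events.jsonl
quitfence run-all --seed 42 --out out/       # everything + feasibility report
```

Traces are CSV, reports/diaries/events JSONL, geofences GeoJSON, profiles
and scenarios YAML; see `docs/methods.md` for the model, its assumptions,
the simulator's calibration, and known limitations.

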