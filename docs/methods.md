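# Methods

## The intervention model

`quitfence` implements a location-aware, just-in-time adaptive intervention
(JITAI) engine for smoking cessation. The behavioural premise is cue
reactivity: cravings are strongest in the places where a person habitually
smoked, so support should arrive when the person is *in* such a place
during a quit attempt. The engine works in three stages anchored on a
user-nominated quit date:

1. **Prepare and learn** (before the quit date). The user logs each
   cigarette in real time with a five-item context assessment — mood (1–5),
   stress (1–5), urge strength (0–5, items in the style of the Mood and
   Physical Symptoms Scale), situation (Home / Working / Socializing /
   Other) and company (and, unless alone, whether the others smoke).
   Located reports are clustered into candidate smoking locations.
2. **Commit to quit** (local days 0–27 from the quit date, a 28-day
   window). Clusters with at least five reports have become circular
   geofences (radius 100 m). Entering a fence and remaining for 5 minutes
   triggers an ENTRY support notification; every further 3 hours of
   continuous presence triggers a DWELL notification. Message content is
   tailored to the fence's aggregated context and to the user's
   demographics/smoking survey.
3. **Maintain the change** (day 28 onward). No further triggers.

Morning notifications are scheduled daily during stages 1–2; end-of-day
(EoD) diaries record the day's cigarettes as a category (0, 1–5, 6–10,
11–15, 16–20, 21+), urges, and abstinence self-efficacy.

## Geofence learning

Reports are assigned incrementally, in arrival order, to the nearest
cluster whose running centroid lies within a proximity threshold (default
100 m, equal to the fence radius so that an activated cluster's members
fall inside their own fence); otherwise the report seeds a new cluster.
Ties break to the earliest-created cluster, making the procedure
deterministic. A cluster activates on reaching the activation threshold
(default 5); its centre freezes at the centroid at that moment and never
moves, mirroring platforms whose registered geofences are static. Later
reports landing within the proximity of a frozen centre join the
membership (feeding tailoring context) without re-centring. "Same
proximity" as distance-to-running-centroid is a modelling choice: the
behaviour is validated against an exhaustive set-packing oracle for small
inputs with well-separated anchors. Overlapping fences are permitted.

Second-generation configuration: `v2_threshold` lowers the activation
count, and `lapse_geofences=True` creates a fence around any located lapse
reported during the quit window that is not already inside an existing
fence.

## Containment and event detection

Distances are haversine on a 6 371 000 m sphere; at geofence scales the
error versus ellipsoidal geodesy is far below the ~30 m accuracy radius of
phone fixes. Containment is **strict** by default: the fix's 68% accuracy
circle must lie entirely inside the fence
(`distance + accuracy ≤ radius`), reproducing the real failure mode in
which poor accuracy suppresses geofence events entirely. Lenient mode
(`distance ≤ radius`) exists for sensitivity analysis.

The trigger engine assumes continuity between consecutive samples: between
two contained samples the user is continuously inside; exit happens at the
timestamp of the first non-contained sample. A 15-minute sampling cadence
cannot resolve anything finer. Both the 5-minute entry confirmation and
the 3-hour dwell clock anchor to presence start (the first contained
sample) and reset fully on exit; when an entry tick and a dwell tick would
coincide, the entry takes precedence. Fences run independent state
machines, so one sample can drive events in several overlapping fences.
Notifications never expire. The engine is verified event-for-event against
a brute-force simulation that advances one second at a time and applies
the definitions literally.

## Message selection

Messages carry a stage tag, a trigger tag (GEOFENCE / MORNING /
POST_REPORT / FEEDBACK), optional situation and stress-band tags, and
optional required profile answers. Selection filters by trigger and stage
(never relaxed) and by profile keys (exact match, also never relaxed),
then by the fence's modal situation (ties resolved Home > Working >
Socializing > Other) and its mean-stress band. Bands on the 1–5 scale are
LOW < 2.5 ≤ MODERATE ≤ 3.5 < HIGH — configuration constants chosen so
MODERATE straddles the midpoint. If no candidate survives, filters relax
in order: stress band first, then situation (situation is the stronger
tailoring signal). Delivered messages are avoided until the candidate set
is exhausted, then the rotation restarts per trigger/stage combination.
The final pick is uniform under a caller-supplied seed, so selection is a
pure, reproducible function of its inputs.

The feedback statistic renders
`Did you know? Based on {n} reports, {p}% of the times you smoke you are
{situation}.` with the percent rounded half-up to an integer; the raw
proportion is also returned. The shipped corpus is a code-generated
placeholder (~50 messages) covering every tag combination, with text
lengths padded toward the mean lengths of deployed content per trigger
type (≈198 geofence / ≈219 post-report / ≈181 morning characters) so
burden simulations are realistic. It contains no authored intervention
content.

## Feasibility metrics

Percentages round half-up to one decimal (two for the overall
message-rating rate); SDs use the n−1 estimator. A day is
**under-reported** when its real-time report count falls below the lower
bound of that day's EoD category — the conservative reading: such a day is
certainly under-reported wherever the truth lies within the category. The
denominator is the number of completed EoD surveys. Reports-per-day uses
each participant's own pre-quit length. Notification response: median/IQR
are computed over opened notifications only, while the within-30-minutes
proportion keeps every generated notification in its denominator; the CDF
right-censors unopened notifications at infinity and therefore plateaus at
the ever-opened proportion. "Delivered" means opened with a message
attached, since tapping the notification is what delivers the content.

## The synthetic cohort generator

Defaults: 15 users, 20 pre-quit days, a 28-day quit window, background
samples every 15 minutes. Each user has a home anchor (≤8 km from a common
base point), a work anchor 1–5 km from home (weekdays 08:30–17:00, with
30-minute linearly interpolated commutes) and a social venue on two
evenings a week. Episode intensities per anchor-day (home 2.0, work 1.55,
social 0.8, other 0.5, Poisson) are thinned by the weekly schedule so the
realized situation mix lands near home 50% / work 31% / social 6% / other
13%, and — at reporting compliance 0.55 — the cohort logs ≈2.0 reports per
participant-day. Episode times are uniform within the anchor's dwell
blocks (the within-day timing distribution is a declared default, not an
inference). Context draws are anchor-conditional (stress skews high at
work, low while socializing; company "alone" is most likely at home) and
are exposed as module constants.

Observation noise: report locations are captured with probability 0.97;
accuracy values are log-normal with mean 31.6 m / SD 16.8 m; positional
error is an isotropic 2-D Gaussian whose 68% containment radius equals the
drawn accuracy (per-axis σ = accuracy/1.5096). EoD diaries are completed
with probability 0.60 pre-quit / 0.39 post-quit and always encode the
*true* daily count's category. Half of users lapse post-quit (first lapse
uniform within ~2.5 weeks, episodes 0.4/day biased toward work).
Notification opens: never-open probability 0.263; otherwise a log-normal
delay with median 23.6 min and σ = 0.519, which places ≈50% of all
generated notifications within 30 minutes; opened messages are rated with
probability 0.78. All randomness derives from `(scenario.seed,
user_index)` substreams.

### What the generator does and does not emulate

It reproduces the quantities the engine's pipeline is calibrated against:
reports per day, situation mix, location-capture rate and accuracy
distribution, diary compliance, open-delay median and 30-minute open
proportion, rating probability, and a geofence yield of roughly one to two
fences per user. It does **not** reproduce several observational features
of real deployments, and passing tests should not be read as matching
them:

* the under-reported-day proportion is ≈25–30%, the value implied by the
  generative model (Poisson daily counts ≈3.8, episode-wise compliance
  0.55), not the ≈56% seen in cohorts that smoke 6–10+ per day while
  logging ≈2 — that combination cannot be produced by any single
  episode-reporting probability consistent with 2 reports/day;
* simulated users dwell inside their fenced anchors far longer than real
  participants did, so the entry/dwell event split skews toward dwell-rich
  presence (≈80/20 entry-heavy on opened counts) and per-user message
  volumes are higher than field deployments report;
* a single rating probability applies to all trigger types;
* the open-delay distribution has a much lighter tail than field data
  (a two-parameter log-normal cannot jointly match a 23.6-minute median,
  a ~78-minute IQR and the 30-minute open proportion; the median and the
  30-minute proportion were prioritised);
* mobility is schedule-driven teleportation with linear commutes — no road
  networks, no day-to-day schedule variation, no indoor positioning
  artefacts.

## Numerical and degenerate-input choices

Timestamps are UTC epoch seconds; files use ISO-8601. Day bucketing
applies a per-user timezone offset (default 0). Stage windows are
half-open at local midnight. Cluster centroids average raw decimal degrees
(valid at sub-kilometre extents). An empty report list yields an empty
fence list; an empty cohort, a zero-event engagement query and a
zero-report feedback request raise errors rather than emitting vacuous
statistics; zero *delivered* messages yields a zero-safe engagement block.
Traces must be strictly increasing in time or are rejected (readers offer
a non-strict mode).

## Problem sizes in the test suite

Oracle-equivalence runs 500 random traces of 10–120 samples at 30–300 s
intervals against the 1-second brute-force simulator; the exhaustive
clustering oracle covers inputs of up to 12 reports; parameter recovery
uses a 200-user cohort (compliance/diary metrics, with a binomial-CDF
expectation computed from ground truth) and 3000-event interaction streams
(rating and open-delay recovery); the anti-monotonicity of under-reporting
in compliance is checked across p ∈ {0.3, 0.55, 0.8, 1.0} on 40-user
cohorts. These sizes give binomial 95% intervals of roughly ±1–2
percentage points on the recovered rates.
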