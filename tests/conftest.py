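import datetime as dt

import pytest

from quitfence.geo import GeoPoint, LocationSample
from quitfence.reporting import Company, Situation, SmokingReport, Stage, UserProfile

ANCHOR = GeoPoint(52.2, 0.12)
QUIT_DATE = dt.date(2016, 3, 27)


@pytest.fixture
def profile():
    return UserProfile(
        user_id="u1",
        quit_date=QUIT_DATE,
        gender="female",
        age_band="25-34",
        cigarettes_per_day_band="6-10",
        first_cigarette_within_30min=True,
        lives_with_smokers=False,
        plans_ecigarette=False,
    )


def make_report(
    report_id="r1",
    timestamp=0.0,
    location=None,
    accuracy_m=None,
    mood=3,
    stress=3,
    urge=3,
    situation=Situation.HOME,
    company=Company.ALONE,
    others_smoking=None,
    stage=Stage.PREPARE_AND_LEARN,
):
    if location is not None and accuracy_m is None:
        accuracy_m = 10.0
    return SmokingReport(
        report_id=report_id,
        timestamp=timestamp,
        mood=mood,
        stress=stress,
        urge_strength=urge,
        situation=situation,
        company=company,
        others_smoking=others_smoking,
        location=location,
        accuracy_m=accuracy_m,
        stage_at_report=stage,
    )


def make_trace(flags_or_positions, t0=0, step_s=60, inside=ANCHOR, outside=None, accuracy=0.0):
    """Build a trace from a string like 'IIOI' (inside/outside) or explicit points."""
    from quitfence.geo import destination

    if outside is None:
        outside = destination(inside, 90.0, 1000.0)
    samples = []
    for k, flag in enumerate(flags_or_positions):
        point = inside if flag == "I" else outside
        samples.append(LocationSample(t0 + k * step_s, point, accuracy))
    return samples
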