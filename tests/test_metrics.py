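import datetime as dt

import numpy as np
import pytest

from conftest import make_report
from quitfence.metrics import (
    CategoryBounds,
    DEFAULT_BOUNDS,
    UserData,
    engagement_rates,
    eod_compliance,
    feasibility_report,
    location_capture,
    response_time_stats,
    underreporting_days,
)
from quitfence.geo import GeoPoint
from quitfence.reporting import EoDSurvey, UserProfile
from quitfence.trigger_engine import EventType, TriggerEvent

DAY = dt.date(2016, 3, 10)


def eod(day=DAY, category="1-5"):
    return EoDSurvey(
        user_id="u1",
        local_date=day,
        cigarettes_category=category,
        urge_strength=3,
        urge_frequency=3,
        abstinence_self_efficacy=3,
    )


def reports_on(day, n):
    t0 = dt.datetime.combine(day, dt.time(9), tzinfo=dt.timezone.utc).timestamp()
    return [make_report(report_id=f"{day}-{i}", timestamp=t0 + i * 300) for i in range(n)]


class TestCategoryBounds:
    def test_partition_of_nonnegative_integers(self):
        for count in range(0, 40):
            label = DEFAULT_BOUNDS.category_for(count)
            lo, hi = DEFAULT_BOUNDS.bounds[label]
            assert lo <= count and (hi is None or count <= hi)

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            DEFAULT_BOUNDS.lower("2-4")


class TestUnderreporting:
    @pytest.mark.parametrize(
        "category, n_reports, under",
        [
            ("6-10", 4, True),   # 4 < 6
            ("1-5", 5, False),   # 5 >= 1
            ("0", 0, False),     # 0 >= 0
            ("21+", 20, True),
            ("1-5", 0, True),
        ],
    )
    def test_day_classification(self, category, n_reports, under):
        got = underreporting_days(reports_on(DAY, n_reports), [eod(category=category)])
        assert got == (int(under), 1, 100.0 * under)

    def test_survey_days_are_denominator(self):
        days = [DAY + dt.timedelta(days=i) for i in range(4)]
        surveys = [eod(day=d, category="1-5") for d in days[:3]]  # day 3 has no survey
        reports = reports_on(days[0], 2)  # only day 0 reported
        under, total, pct = underreporting_days(reports, surveys)
        assert (under, total, pct) == (2, 3, 66.7)


class TestEodCompliance:
    def test_printed_pre_quit_rate(self):
        days = [DAY + dt.timedelta(days=i) for i in range(250)]
        surveys = [eod(day=d) for d in days[:150]]
        assert eod_compliance(surveys, (days[0], days[-1])) == (150, 250, 60.0)

    def test_zero_and_full(self):
        period = (DAY, DAY + dt.timedelta(days=9))
        assert eod_compliance([], period) == (0, 10, 0.0)
        surveys = [eod(day=DAY + dt.timedelta(days=i)) for i in range(10)]
        assert eod_compliance(surveys, period) == (10, 10, 100.0)


class TestLocationCapture:
    def test_share_with_fix(self):
        p = GeoPoint(52.2, 0.12)
        located = [
            make_report(report_id=f"l{i}", timestamp=float(i), location=p, accuracy_m=a)
            for i, a in enumerate([10.0, 20.0, 30.0])
        ]
        missing = [make_report(report_id="m0", timestamp=99.0)]
        n, total, pct, mean, sd = location_capture(located + missing)
        assert (n, total, pct) == (3, 4, 75.0)
        assert mean == pytest.approx(20.0)
        assert sd == pytest.approx(10.0)  # n-1 estimator

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            location_capture([])


def event(i, etype=EventType.ENTRY, opened_delay_min=None, message=False, rating=None):
    e = TriggerEvent(
        f"e{i}",
        etype,
        generated_at=1000.0 + i,
        geofence_id="f0" if etype in (EventType.ENTRY, EventType.DWELL) else None,
        opened_at=None if opened_delay_min is None else 1000.0 + i + opened_delay_min * 60,
        message_id=f"m{i}" if message else None,
        rating=rating,
    )
    return e


class TestResponseTime:
    def test_hand_computed_mixture(self):
        events = [
            event(0, opened_delay_min=10),
            event(1, opened_delay_min=20),
            event(2, opened_delay_min=40),
            event(3),  # never opened
        ]
        stats = response_time_stats(events)
        assert stats.median_min == pytest.approx(20.0)
        assert stats.proportion_within == pytest.approx(2 / 4)
        assert stats.n_generated == 4 and stats.n_opened == 3

    def test_all_instant(self):
        events = [event(i, opened_delay_min=0) for i in range(5)]
        stats = response_time_stats(events)
        assert stats.median_min == 0.0 and stats.proportion_within == 1.0

    def test_cdf_monotone_and_bounded_by_open_rate(self):
        rng = np.random.default_rng(1)
        events = [
            event(i, opened_delay_min=float(rng.uniform(0, 300)) if rng.random() < 0.7 else None)
            for i in range(60)
        ]
        stats = response_time_stats(events)
        fracs = [f for _, f in stats.cdf]
        assert fracs == sorted(fracs)
        assert fracs[-1] == pytest.approx(stats.n_opened / stats.n_generated)

    def test_no_events_is_error(self):
        with pytest.raises(ValueError):
            response_time_stats([])


class TestEngagement:
    def test_rates_and_split(self):
        events = (
            [event(i, EventType.ENTRY, opened_delay_min=5, message=True, rating=4) for i in range(3)]
            + [event(10 + i, EventType.DWELL, opened_delay_min=5, message=True) for i in range(2)]
            + [event(20 + i, EventType.MORNING, opened_delay_min=5, message=True) for i in range(5)]
            + [event(30)]  # generated but never delivered
        )
        e = engagement_rates(events)
        assert e.n_delivered == 10 and e.n_rated == 3
        assert e.geofence_delivered == 5
        assert (e.geofence_entry, e.geofence_dwell) == (3, 2)
        assert e.percent_entry == 60.0 and e.percent_dwell == 40.0

    def test_zero_delivered_is_zero_safe(self):
        e = engagement_rates([event(0)])
        assert e.n_delivered == 0 and e.percent_rated == 0.0


class TestFeasibilityReport:
    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError):
            feasibility_report([])

    def test_triples_internally_consistent_on_simulated_cohort(self):
        from quitfence.pipeline import PipelineConfig, process_user
        from quitfence.simulator import SimScenario, simulate_cohort

        scenario = SimScenario(seed=11, n_users=4)
        cohort = simulate_cohort(scenario)
        config = PipelineConfig(scenario=scenario)
        users = [process_user(s, config) for s in cohort.users]
        report = feasibility_report(users)
        d = report.to_dict()
        for key in ("underreporting", "location_capture"):
            block = d[key]
            n, total = list(block.values())[0], list(block.values())[1]
            pct = list(block.values())[2]
            assert 0 <= pct <= 100
            assert n <= total
            assert pct == pytest.approx(100.0 * n / total, abs=0.05)
        assert d["messages_rated"]["n"] <= d["messages_rated"]["n_delivered"]
        assert sum(v["n"] for v in d["situation_counts"].values()) == d["situation_total"]
        assert report.to_table()  # renders without error

    def test_underreporting_anti_monotone_in_compliance(self):
        from quitfence.simulator import SimScenario, simulate_user

        proportions = []
        for p in (0.3, 0.55, 0.8, 1.0):
            under = total = 0
            for seed in (0, 1):
                scenario = SimScenario(seed=seed, n_users=6, report_compliance_p=p)
                for i in range(scenario.n_users):
                    sim = simulate_user(scenario, i)
                    pre = [
                        r for r in sim.reports
                        if r.timestamp < dt.datetime.combine(
                            sim.profile.quit_date, dt.time(0), tzinfo=dt.timezone.utc
                        ).timestamp()
                    ]
                    pre_eods = [s for s in sim.eods if s.local_date < sim.profile.quit_date]
                    u, t, _ = underreporting_days(pre, pre_eods)
                    under += u
                    total += t
            proportions.append(under / total)
        assert proportions == sorted(proportions, reverse=True)
        assert proportions[-1] == 0.0  # full compliance never under-reports
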