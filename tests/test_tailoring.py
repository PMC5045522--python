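import datetime as dt

import pytest

from conftest import ANCHOR, QUIT_DATE, make_report
from quitfence.corpus import (
    TARGET_LENGTHS,
    placeholder_corpus,
    read_corpus_csv,
    write_corpus_csv,
)
from quitfence.geo import Geofence
from quitfence.reporting import Company, Situation, Stage
from quitfence.tailoring import (
    MessageSelector,
    NoContentError,
    StressBand,
    SupportMessage,
    TriggerTag,
    context_profile,
    feedback_message,
    select_message,
    stress_band,
)
from quitfence.trigger_engine import EventType, TriggerEvent

COMMIT_TS = dt.datetime.combine(
    QUIT_DATE + dt.timedelta(days=2), dt.time(10), tzinfo=dt.timezone.utc
).timestamp()


def member_reports(specs):
    """specs: list of dicts with stress/situation overrides."""
    return [
        make_report(report_id=f"m{i}", timestamp=float(i), location=ANCHOR, **spec)
        for i, spec in enumerate(specs)
    ]


def fence_for(reports):
    return Geofence(
        id="f0",
        center=ANCHOR,
        radius_m=100.0,
        member_report_ids=frozenset(r.report_id for r in reports),
    )


class TestStressBand:
    @pytest.mark.parametrize(
        "mean, band",
        [
            (1.0, StressBand.LOW),
            (2.4999, StressBand.LOW),
            (2.5, StressBand.MODERATE),
            (3.0, StressBand.MODERATE),
            (3.5, StressBand.MODERATE),
            (4.33, StressBand.HIGH),
            (5.0, StressBand.HIGH),
        ],
    )
    def test_cut_points(self, mean, band):
        assert stress_band(mean) is band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            stress_band(0.5)


class TestContextProfile:
    def test_mean_stress_and_band(self):
        reports = member_reports([{"stress": 4}, {"stress": 4}, {"stress": 5}])
        ctx = context_profile(fence_for(reports), reports)
        assert ctx.mean_stress == pytest.approx(13 / 3)
        assert stress_band(ctx.mean_stress) is StressBand.HIGH

    def test_all_home(self):
        reports = member_reports([{"situation": Situation.HOME}] * 3)
        ctx = context_profile(fence_for(reports), reports)
        assert ctx.modal_situation is Situation.HOME
        assert ctx.situation_proportions[Situation.HOME] == 1.0

    def test_tie_breaks_by_priority(self):
        reports = member_reports(
            [{"situation": Situation.WORKING}] * 2 + [{"situation": Situation.HOME}] * 2
        )
        ctx = context_profile(fence_for(reports), reports)
        assert ctx.modal_situation is Situation.HOME

    def test_company_smoking_proportion(self):
        reports = member_reports(
            [
                {"company": Company.COLLEAGUES, "others_smoking": True},
                {"company": Company.COLLEAGUES, "others_smoking": False},
                {},
            ]
        )
        ctx = context_profile(fence_for(reports), reports)
        assert ctx.company_smoking_proportion == pytest.approx(1 / 3)

    def test_no_members_is_error(self):
        fence = Geofence(id="f", center=ANCHOR, radius_m=100.0)
        with pytest.raises(ValueError):
            context_profile(fence, [])


def msg(mid, trigger=TriggerTag.GEOFENCE, stage=Stage.COMMIT_TO_QUIT, **kw):
    return SupportMessage(message_id=mid, text="x" * 50, stage_tag=stage, trigger_tag=trigger, **kw)


def entry_event():
    return TriggerEvent("e1", EventType.ENTRY, COMMIT_TS, geofence_id="f0")


class TestSelectMessage:
    def ctx(self, stress=4.0, situation=Situation.HOME):
        reports = member_reports([{"stress": 4, "situation": situation}] * 3)
        c = context_profile(fence_for(reports), reports)
        c.mean_stress = stress
        return c

    def test_single_match(self, profile):
        pool = [msg("only")]
        assert select_message(pool, entry_event(), None, profile, set(), seed=0).message_id == "only"

    def test_seeded_determinism(self, profile):
        pool = [msg("a"), msg("b")]
        picks = {
            select_message(pool, entry_event(), None, profile, set(), seed=11).message_id
            for _ in range(5)
        }
        assert len(picks) == 1

    def test_tag_filtering_prefers_full_match(self, profile):
        pool = [
            msg("generic"),
            msg("situated", situation_tag=Situation.HOME, stress_band_tag=StressBand.HIGH),
            msg("wrong", situation_tag=Situation.WORKING),
        ]
        picked = {
            select_message(pool, entry_event(), self.ctx(), profile, set(), seed=s).message_id
            for s in range(20)
        }
        assert "wrong" not in picked
        assert picked <= {"generic", "situated"}

    def test_relaxation_drops_stress_band_first(self, profile):
        pool = [msg("home-low", situation_tag=Situation.HOME, stress_band_tag=StressBand.LOW)]
        # context is HIGH stress; only a LOW-tagged home message exists -> band relaxes
        assert (
            select_message(pool, entry_event(), self.ctx(), profile, set(), seed=0).message_id
            == "home-low"
        )

    def test_trigger_and_stage_never_relax(self, profile):
        pool = [msg("morning-only", trigger=TriggerTag.MORNING)]
        with pytest.raises(NoContentError):
            select_message(pool, entry_event(), None, profile, set(), seed=0)

    def test_profile_keys_are_hard_filter(self, profile):
        pool = [
            msg("mismatched", profile_keys=(("lives_with_smokers", "True"),)),
            msg("matched", profile_keys=(("lives_with_smokers", "False"),)),
        ]
        for s in range(10):
            assert (
                select_message(pool, entry_event(), None, profile, set(), seed=s).message_id
                == "matched"
            )

    def test_no_repeat_until_exhaustion(self, profile):
        pool = [msg(f"m{i}") for i in range(3)]
        selector = MessageSelector(pool, seed=5)
        picks = [selector.select(entry_event(), None, profile).message_id for _ in range(5)]
        assert set(picks[:3]) == {"m0", "m1", "m2"}  # all appear before any repeat
        assert picks[3] in {"m0", "m1", "m2"}

    def test_purity_history_not_mutated(self, profile):
        history = {"a"}
        select_message([msg("a"), msg("b")], entry_event(), None, profile, history, seed=0)
        assert history == {"a"}


class TestFeedbackMessage:
    def test_worked_example_twelve_reports(self):
        reports = [
            make_report(report_id=f"r{i}", timestamp=float(i),
                        situation=Situation.WORKING if i < 3 else Situation.HOME)
            for i in range(12)
        ]
        text, n, percent = feedback_message(reports, Situation.WORKING)
        assert (n, percent) == (12, 25.0)
        assert text == (
            "Did you know? Based on 12 reports, 25% of the times you smoke you are working."
        )

    def test_all_home(self):
        reports = [make_report(report_id=f"r{i}", timestamp=float(i)) for i in range(10)]
        text, n, percent = feedback_message(reports, Situation.HOME)
        assert percent == 100.0 and "100% of the times you smoke you are at home" in text

    def test_two_of_eight_socializing(self):
        reports = [
            make_report(report_id=f"r{i}", timestamp=float(i),
                        situation=Situation.SOCIALIZING if i < 2 else Situation.OTHER)
            for i in range(8)
        ]
        _, _, percent = feedback_message(reports, Situation.SOCIALIZING)
        assert percent == 25.0

    def test_zero_reports_is_error(self):
        with pytest.raises(ValueError):
            feedback_message([], Situation.HOME)

    def test_percentages_sum_to_100(self):
        import numpy as np

        rng = np.random.default_rng(0)
        reports = [
            make_report(report_id=f"r{i}", timestamp=float(i),
                        situation=list(Situation)[int(rng.integers(4))])
            for i in range(17)
        ]
        total = sum(feedback_message(reports, s)[2] for s in Situation)
        assert total == pytest.approx(100.0)


class TestPlaceholderCorpus:
    def test_size_and_tags(self):
        corpus = placeholder_corpus()
        assert 40 <= len(corpus) <= 60
        assert len({m.message_id for m in corpus}) == len(corpus)
        assert all(m.text for m in corpus)

    @pytest.mark.parametrize("trigger", [TriggerTag.GEOFENCE, TriggerTag.POST_REPORT, TriggerTag.MORNING])
    def test_mean_lengths_near_targets(self, trigger):
        lengths = [len(m.text) for m in placeholder_corpus() if m.trigger_tag is trigger]
        assert abs(sum(lengths) / len(lengths) - TARGET_LENGTHS[trigger]) <= 25

    def test_every_situation_band_combination_covered(self):
        corpus = placeholder_corpus()
        combos = {
            (m.situation_tag, m.stress_band_tag)
            for m in corpus
            if m.trigger_tag is TriggerTag.GEOFENCE and m.situation_tag
        }
        assert {(s, b) for s in Situation for b in StressBand} <= combos

    def test_csv_round_trip(self, tmp_path):
        corpus = placeholder_corpus()
        path = tmp_path / "corpus.csv"
        write_corpus_csv(corpus, path)
        assert read_corpus_csv(path) == corpus
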