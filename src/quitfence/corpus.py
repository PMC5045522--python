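"""Placeholder support-message corpus.

The real intervention content is authored by behaviour-change specialists
and is not reproduced here; this module generates a synthetic stand-in
corpus with the same schema and tagging structure so the selection and
delivery machinery can be exercised end to end. Message lengths are padded
toward the mean lengths observed for deployed content of each trigger type
(about 198 characters for geofence messages, 219 for post-report lapse
support, 181 for morning messages) so that burden simulations are
realistic.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

from .reporting import Situation, Stage
from .tailoring import StressBand, SupportMessage, TriggerTag

TARGET_LENGTHS = {
    TriggerTag.GEOFENCE: 198,
    TriggerTag.POST_REPORT: 219,
    TriggerTag.MORNING: 181,
    TriggerTag.FEEDBACK: 150,
}

_FILLERS = (
    " A short walk, a glass of water, or a quick call to a friend can carry you past the urge.",
    " Take a slow breath and give the craving a minute to pass before acting on it.",
    " Remind yourself why you decided to stop and what you stand to gain.",
    " Every craving you ride out makes the next one easier.",
    " Cravings fade within minutes.",
    " Keep your hands busy.",
    " Stay with it.",
)


def _pad(base: str, target: int, salt: int) -> str:
    # Greedily append coping-tip sentences of assorted lengths until the
    # text sits close to the target character count.
    text = base
    i = salt
    while len(text) < target - 8:
        remaining = target - len(text)
        filler = next(
            (f for f in _FILLERS[i % len(_FILLERS):] + _FILLERS[: i % len(_FILLERS)]
             if len(f) <= remaining + 8),
            _FILLERS[-1],
        )
        text += filler
        i += 1
    return text


def placeholder_corpus() -> list[SupportMessage]:
    """A deterministic ~50-message synthetic corpus covering every tag combination."""
    messages: list[SupportMessage] = []
    counter = 0

    def add(
        base: str,
        stage: Stage,
        trigger: TriggerTag,
        situation: Situation | None = None,
        band: StressBand | None = None,
        profile_keys: tuple[tuple[str, str], ...] = (),
    ) -> None:
        nonlocal counter
        counter += 1
        messages.append(
            SupportMessage(
                message_id=f"msg-{counter:03d}",
                text=_pad(base, TARGET_LENGTHS[trigger], counter),
                stage_tag=stage,
                trigger_tag=trigger,
                situation_tag=situation,
                stress_band_tag=band,
                profile_keys=profile_keys,
            )
        )

    situation_phrases = {
        Situation.HOME: "You are somewhere you used to smoke at home.",
        Situation.WORKING: "You are in a place where you often smoked while working.",
        Situation.SOCIALIZING: "You are in a spot where smoking went with socializing.",
        Situation.OTHER: "You are near one of your old smoking spots.",
    }
    band_phrases = {
        StressBand.LOW: "Things have felt calm here before — keep that going without a cigarette.",
        StressBand.MODERATE: "This place has come with some stress — plan how you will handle it.",
        StressBand.HIGH: "You have often felt very stressed here — be ready with a coping strategy.",
    }
    # Geofence-triggered content: one message per situation x stress band, plus generics.
    for situation, sp in situation_phrases.items():
        for band, bp in band_phrases.items():
            add(f"{sp} {bp}", Stage.COMMIT_TO_QUIT, TriggerTag.GEOFENCE, situation, band)
        add(f"{sp} Stay on guard here.", Stage.COMMIT_TO_QUIT, TriggerTag.GEOFENCE, situation)
    for i in range(4):
        add(
            "You have entered one of your smoking locations. This is a high-risk moment.",
            Stage.COMMIT_TO_QUIT,
            TriggerTag.GEOFENCE,
        )

    # Morning content: preparation facts pre-quit, encouragement in the quit window.
    for i in range(6):
        add(
            f"Good morning. Preparation tip {i + 1}: notice when and where you smoke today.",
            Stage.PREPARE_AND_LEARN,
            TriggerTag.MORNING,
        )
        add(
            f"Good morning. Day-by-day encouragement {i + 1}: staying smoke-free pays off fast.",
            Stage.COMMIT_TO_QUIT,
            TriggerTag.MORNING,
        )

    # Post-report lapse/relapse-prevention content.
    for i in range(6):
        add(
            f"A slip is not a fall. Lapse recovery step {i + 1}: treat this as one moment, "
            "not the end of your attempt.",
            Stage.COMMIT_TO_QUIT,
            TriggerTag.POST_REPORT,
        )
    add(
        "Living with other smokers makes quitting harder; agree some smoke-free rooms today.",
        Stage.COMMIT_TO_QUIT,
        TriggerTag.POST_REPORT,
        profile_keys=(("lives_with_smokers", "True"),),
    )
    add(
        "Your home is smoke-free; keep it that way and let it anchor your quit attempt.",
        Stage.COMMIT_TO_QUIT,
        TriggerTag.POST_REPORT,
        profile_keys=(("lives_with_smokers", "False"),),
    )

    # Feedback shells (the rendered statistic is produced separately).
    for stage in (Stage.PREPARE_AND_LEARN, Stage.COMMIT_TO_QUIT):
        add("Here is a summary of your recorded smoking patterns.", stage, TriggerTag.FEEDBACK)
    return messages


def write_corpus_csv(messages: Iterable[SupportMessage], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["message_id", "text", "stage_tag", "trigger_tag", "situation_tag", "stress_band_tag", "profile_keys"]
        )
        for m in messages:
            writer.writerow(
                [
                    m.message_id,
                    m.text,
                    m.stage_tag.value,
                    m.trigger_tag.value,
                    m.situation_tag.value if m.situation_tag else "",
                    m.stress_band_tag.value if m.stress_band_tag else "",
                    json.dumps(dict(m.profile_keys)),
                ]
            )


def read_corpus_csv(path: str | Path) -> list[SupportMessage]:
    messages = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            messages.append(
                SupportMessage(
                    message_id=row["message_id"],
                    text=row["text"],
                    stage_tag=Stage(row["stage_tag"]),
                    trigger_tag=TriggerTag(row["trigger_tag"]),
                    situation_tag=Situation(row["situation_tag"]) if row["situation_tag"] else None,
                    stress_band_tag=(
                        StressBand(row["stress_band_tag"]) if row["stress_band_tag"] else None
                    ),
                    profile_keys=tuple(sorted(json.loads(row["profile_keys"] or "{}").items())),
                )
            )
    return messages


__all__ = ["TARGET_LENGTHS", "placeholder_corpus", "write_corpus_csv", "read_corpus_csv"]
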