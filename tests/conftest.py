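import pytest
from hypothesis import HealthCheck, settings

from rmetnet import (
    AnswerKey,
    ItemSpec,
    ResponseRecord,
    SimConfig,
    simulate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_item(item_id=1, target="calm", distractors=("angry", "sad", "shy"), valence="neutral"):
    return ItemSpec(
        item_id=item_id, target=target, distractors=tuple(distractors), valence=valence
    )


def make_records(choices_by_participant, key, group="A", rt=3000.0):
    """Build a full-coverage record list from {pid: {item_id: choice}}."""
    records = []
    for pid, by_item in choices_by_participant.items():
        for item in key:
            choice = by_item[item.item_id]
            records.append(
                ResponseRecord(
                    participant_id=pid,
                    group=group,
                    item_id=item.item_id,
                    choice=choice,
                    rt_ms=None if choice == "NR" else rt,
                )
            )
    return records


@pytest.fixture()
def tiny_key():
    """Two items sharing the distractor word 'sad'."""
    return AnswerKey(
        items=(
            ItemSpec(1, "calm", ("angry", "sad", "shy"), "neutral"),
            ItemSpec(2, "happy", ("sad", "bored", "tense"), "positive"),
        )
    )


@pytest.fixture(scope="session")
def study_cohort():
    """Default study-shaped synthetic cohort (30+30, 43 items, 19/15/9)."""
    cfg = SimConfig(seed=1234)
    responses, key, traits = simulate_cohort(cfg)
    return responses, key, traits
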