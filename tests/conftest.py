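import datetime as dt
import random

import pytest
from hypothesis import strategies as st

from anodon.envelope import generate_keypair
from anodon.payload import (
    CATEGORIES,
    DEFAULT_QUESTIONNAIRE_VOCAB,
    DonationPayload,
    HealthRecordRow,
    QuestionnaireEntry,
)


@pytest.fixture(scope="session")
def keypair():
    """One 2048-bit donation keypair shared across the suite (seeded)."""
    return generate_keypair(2048, random.Random(0xA5EED))


def random_payload(rng: random.Random, max_rows: int = 20) -> DonationPayload:
    """Small random but valid payload for round-trip and crypto tests."""
    rows = []
    for _ in range(rng.randrange(max_rows + 1)):
        category = rng.choice(CATEGORIES)
        date = dt.date(2024, 1, 1) + dt.timedelta(days=rng.randrange(365))
        value = round(rng.uniform(0.5, 250), rng.randrange(4))
        analyte = rng.choice(["ldl", "hdl", "glucose"]) if category == "lab_result" else ""
        rows.append(HealthRecordRow(category, date, value, analyte))
    questionnaire = []
    for key in rng.sample(list(DEFAULT_QUESTIONNAIRE_VOCAB), rng.randrange(4)):
        questionnaire.append(
            QuestionnaireEntry(key, rng.choice(DEFAULT_QUESTIONNAIRE_VOCAB[key]))
        )
    return DonationPayload(rows=tuple(rows), questionnaire=tuple(questionnaire))


# ------------------------------------------------------------ hypothesis

finite_values = st.floats(allow_nan=False, allow_infinity=False, width=64)

health_rows = st.builds(
    lambda category, date, value, analyte: HealthRecordRow(
        category, date, value, analyte if category == "lab_result" else ""
    ),
    category=st.sampled_from(CATEGORIES),
    date=st.dates(),
    value=finite_values,
    analyte=st.text(
        alphabet=st.characters(blacklist_categories=("Cs",), blacklist_characters="\x00"),
        max_size=12,
    ),
)

questionnaire_entries = st.sampled_from(
    [
        QuestionnaireEntry(key, answer)
        for key, answers in DEFAULT_QUESTIONNAIRE_VOCAB.items()
        for answer in answers
    ]
)

payloads = st.builds(
    lambda rows, q: DonationPayload(rows=tuple(rows), questionnaire=tuple(q)),
    rows=st.lists(health_rows, max_size=12),
    q=st.lists(questionnaire_entries, max_size=5, unique_by=lambda e: e.key),
)
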