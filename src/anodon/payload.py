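"""Donation payload model, CSV wire format, schema validation and identifier screening.

A donation is a complete, identifier-free snapshot of one user's health
dataset: a list of dated per-category measurement rows plus closed-vocabulary
questionnaire answers.  The type deliberately has no donor-id, pseudonym or
partial-donation field — only single, full donations of the whole dataset are
possible, because nothing exists to link partial donations back together.

The CSV dialect is pinned (RFC 4180, comma, UTF-8, LF, minimal quoting, fixed
column order) so that serialization is byte-deterministic: downstream row
hashing for duplicate detection and ciphertext comparisons in tests both rely
on equal payloads producing identical bytes.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml

CATEGORIES = (
    "steps",
    "resting_heart_rate",
    "blood_pressure_systolic",
    "blood_pressure_diastolic",
    "sleep_duration",
    "lab_result",
)

#: fixed CSV column order; header is always present
CSV_COLUMNS = ("section", "category", "observed_date", "value", "analyte", "key", "answer")

SECTION_HEALTH = "health"
SECTION_QUESTIONNAIRE = "questionnaire"

#: closed questionnaire vocabulary: key -> admissible answers
DEFAULT_QUESTIONNAIRE_VOCAB: dict[str, tuple[str, ...]] = {
    "smoking_status": ("never", "former", "current"),
    "diabetes_diagnosed": ("yes", "no"),
    "hypertension_diagnosed": ("yes", "no"),
    "family_history_cvd": ("yes", "no", "unknown"),
    "physical_activity_level": ("low", "moderate", "high"),
    "alcohol_consumption": ("none", "occasional", "regular"),
    "age_decade": ("18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+"),
    "sex": ("female", "male", "diverse"),
    "medication_statin": ("yes", "no"),
    "medication_antihypertensive": ("yes", "no"),
}


class SchemaError(ValueError):
    """Raised when bytes fail CSV schema validation; names the first bad line."""

    def __init__(self, line: int, reason: str):
        super().__init__(f"line {line}: {reason}")
        self.line = line
        self.reason = reason


def render_value(value: float) -> str:
    """Canonical decimal rendering: integral values without a decimal point,
    otherwise the shortest string that round-trips through ``float``."""
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(value)


@dataclass(frozen=True)
class HealthRecordRow:
    """One dated measurement: category, ISO date, finite value, optional analyte.

    ``analyte`` is a short label (e.g. ``ldl``) and only meaningful for
    ``lab_result`` rows, where units are analyte-specific.
    """

    category: str
    observed_date: _dt.date
    value: float
    analyte: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not isinstance(self.observed_date, _dt.date):
            raise ValueError("observed_date must be a date")
        if not math.isfinite(self.value):
            raise ValueError("value must be finite")
        if self.analyte and self.category != "lab_result":
            raise ValueError("analyte only allowed for lab_result rows")


@dataclass(frozen=True)
class QuestionnaireEntry:
    """One closed-vocabulary questionnaire answer (no free text by design)."""

    key: str
    answer: str


@dataclass(frozen=True)
class DonationPayload:
    """A complete snapshot of one user's dataset; carries no identifier of any kind."""

    rows: tuple[HealthRecordRow, ...] = ()
    questionnaire: tuple[QuestionnaireEntry, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "questionnaire", tuple(self.questionnaire))

    @property
    def n_rows(self) -> int:
        return len(self.rows) + len(self.questionnaire)


@dataclass(frozen=True)
class ForbiddenFieldPolicy:
    """Names and regex patterns that must never appear as a field label.

    The policy covers direct identifiers (name, email, phone), location and
    hardware fingerprints (GPS, device id, MAC, IP) and data classes that are
    identifying by nature (ECG waveforms, genetic data).  Screening rejects a
    payload rather than redacting it: the client must fix its snapshot.
    """

    forbidden_names: frozenset[str]
    patterns: tuple[str, ...]
    _compiled: tuple[re.Pattern, ...] = field(default=(), repr=False, compare=False)

    def __post_init__(self):
        if not self.forbidden_names and not self.patterns:
            raise ValueError("policy must not be empty")
        object.__setattr__(
            self, "_compiled", tuple(re.compile(p) for p in self.patterns)
        )

    def matches(self, name: str) -> bool:
        low = name.lower()
        if low in self.forbidden_names:
            return True
        return any(p.search(name) for p in self._compiled)

    @classmethod
    def from_yaml(cls, text: str) -> "ForbiddenFieldPolicy":
        doc = yaml.safe_load(text)
        return cls(
            forbidden_names=frozenset(n.lower() for n in doc.get("forbidden_names", [])),
            patterns=tuple(doc.get("patterns", [])),
        )


def default_policy() -> ForbiddenFieldPolicy:
    text = resources.files("anodon.data").joinpath("forbidden_fields.yaml").read_text()
    return ForbiddenFieldPolicy.from_yaml(text)


def serialize_csv(payload: DonationPayload) -> bytes:
    """Serialize a payload to canonical CSV bytes (UTF-8, LF, fixed columns).

    Deterministic: equal payloads yield byte-identical output.
    """
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    w.writerow(CSV_COLUMNS)
    for r in payload.rows:
        w.writerow(
            [SECTION_HEALTH, r.category, r.observed_date.isoformat(),
             render_value(r.value), r.analyte, "", ""]
        )
    for q in payload.questionnaire:
        w.writerow([SECTION_QUESTIONNAIRE, "", "", "", "", q.key, q.answer])
    return buf.getvalue().encode("utf-8")


def parse_csv(
    data: bytes,
    vocabulary: dict[str, tuple[str, ...]] | None = None,
) -> DonationPayload:
    """Parse and schema-validate CSV bytes into a payload.

    Validation is strict and reports the first offending line: exact header,
    column count, known section and category, ISO-8601 date, finite numeric
    value, analyte only on lab rows, questionnaire keys/answers from the
    closed vocabulary.  Raises :class:`SchemaError` on the first violation.
    """
    vocab = DEFAULT_QUESTIONNAIRE_VOCAB if vocabulary is None else vocabulary
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError as e:
        raise SchemaError(0, f"not valid UTF-8: {e}") from None
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError(1, "missing header row") from None
    if tuple(header) != CSV_COLUMNS:
        raise SchemaError(1, f"bad header {header!r}")

    rows: list[HealthRecordRow] = []
    entries: list[QuestionnaireEntry] = []
    for lineno, rec in enumerate(reader, start=2):
        if len(rec) != len(CSV_COLUMNS):
            raise SchemaError(lineno, f"expected {len(CSV_COLUMNS)} columns, got {len(rec)}")
        section, category, date_s, value_s, analyte, key, answer = rec
        if section == SECTION_HEALTH:
            if key or answer:
                raise SchemaError(lineno, "health row must leave key/answer empty")
            if category not in CATEGORIES:
                raise SchemaError(lineno, f"unknown category {category!r}")
            try:
                date = _dt.date.fromisoformat(date_s)
            except ValueError:
                raise SchemaError(lineno, f"bad date {date_s!r}") from None
            try:
                value = float(value_s)
            except ValueError:
                raise SchemaError(lineno, f"non-numeric value {value_s!r}") from None
            if not math.isfinite(value):
                raise SchemaError(lineno, f"non-finite value {value_s!r}")
            if analyte and category != "lab_result":
                raise SchemaError(lineno, "analyte only allowed on lab_result rows")
            rows.append(HealthRecordRow(category, date, value, analyte))
        elif section == SECTION_QUESTIONNAIRE:
            if category or date_s or value_s or analyte:
                raise SchemaError(lineno, "questionnaire row must leave health columns empty")
            if key not in vocab:
                raise SchemaError(lineno, f"unknown questionnaire key {key!r}")
            if answer not in vocab[key]:
                raise SchemaError(lineno, f"answer {answer!r} not admissible for {key!r}")
            entries.append(QuestionnaireEntry(key, answer))
        else:
            raise SchemaError(lineno, f"unknown section {section!r}")
    return DonationPayload(rows=tuple(rows), questionnaire=tuple(entries))


@dataclass(frozen=True)
class ScreeningViolation:
    location: str  # "questionnaire" | "analyte"
    name: str


@dataclass(frozen=True)
class ScreeningReport:
    violations: tuple[ScreeningViolation, ...]

    @property
    def passed(self) -> bool:
        return not self.violations


def screen_identifiers(
    payload: DonationPayload, policy: ForbiddenFieldPolicy | None = None
) -> ScreeningReport:
    """List every field label in the payload that matches the forbidden policy.

    The payload passes iff the list is empty.  Screening never modifies the
    payload: an offending snapshot is rejected, not repaired.  Only field
    labels are screened — questionnaire keys and lab analyte labels, the
    only free-ish strings the schema admits.
    """
    if policy is None:
        policy = default_policy()
    found: list[ScreeningViolation] = []
    for q in payload.questionnaire:
        if policy.matches(q.key):
            found.append(ScreeningViolation("questionnaire", q.key))
    for r in payload.rows:
        if r.analyte and policy.matches(r.analyte):
            found.append(ScreeningViolation("analyte", r.analyte))
    return ScreeningReport(violations=tuple(found))
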