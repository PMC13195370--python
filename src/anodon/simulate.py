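"""Synthetic donor-cohort generator and end-to-end scenario runner.

The generator emulates the conditions the donation architecture faces in the
field: donors who re-donate their complete, growing dataset every quarter
(so later snapshots are near-supersets of earlier ones, modulo client-side
edits and deletions), per-category physiological value distributions chosen
to sit inside the plausibility intervals, and a configurable fraction of
adversarial clients that emit malformed or implausible payloads.  Every
emitted donation is labeled with its generating donor in a ground-truth
object that is never transmitted, so identifier-free deduplication can be
scored as a parameter-recovery problem.

Donors accrue rows by independent per-category Poisson processes.  Donor
enrollment is spread evenly across the feasible window so a one-year horizon
yields one to four quarterly donations per donor.  Everything derives from a
single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import datetime as _dt
import random
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import client as client_mod
from .curation import (
    DEFAULT_OVERLAP_THRESHOLD,
    cluster_donations,
    plausibility_filter,
)
from .envelope import encrypt, generate_keypair
from .payload import (
    DEFAULT_QUESTIONNAIRE_VOCAB,
    DonationPayload,
    HealthRecordRow,
    QuestionnaireEntry,
    serialize_csv,
)
from .proxy import ProxyServer, assert_stateless, audit_blindness
from .server import DonationServer, DonationStore, DonationStatus, export_donations
from .wire import Status, TransferEnvelope

BASE_DATE = _dt.date(2024, 1, 1)

#: mean new rows per day for each category
DEFAULT_RECORDS_PER_DAY: dict[str, float] = {
    "steps": 1.0,
    "resting_heart_rate": 1.0,
    "sleep_duration": 1.0,
    "blood_pressure_systolic": 0.3,
    "blood_pressure_diastolic": 0.3,
    "lab_result": 0.05,
}

_LAB_PANEL = {
    "cholesterol_total": (195.0, 35.0),
    "ldl": (120.0, 30.0),
    "hdl": (55.0, 14.0),
    "glucose": (95.0, 18.0),
    "hba1c": (5.5, 0.6),
}

ADVERSARIAL_ARCHETYPES = ("bad_schema", "forbidden_field", "implausible", "garbage")


@dataclass(frozen=True)
class CohortConfig:
    n_donors: int = 50
    horizon_days: int = 365
    period_days: int = 90
    records_per_day: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RECORDS_PER_DAY)
    )
    edit_rate: float = 0.05
    adversarial_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_donors < 0:
            raise ValueError("n_donors must be >= 0")
        if not 0 <= self.edit_rate <= 1:
            raise ValueError("edit_rate must be in [0,1]")
        if not 0 <= self.adversarial_fraction <= 1:
            raise ValueError("adversarial_fraction must be in [0,1]")
        if any(r < 0 for r in self.records_per_day.values()):
            raise ValueError("accrual rates must be >= 0")


@dataclass(frozen=True)
class EmittedDonation:
    """One donation on the wire: plaintext bytes plus simulator-side labels.

    ``payload`` is the structured form when the plaintext is well-formed CSV
    (clean and ``implausible`` donations); ``None`` for byte garbage.  The
    labels exist only in the simulator — nothing identifying is serialized.
    """

    index: int
    donor: int
    day: int
    kind: str  # "clean" or an adversarial archetype
    plaintext: bytes
    payload: DonationPayload | None


@dataclass
class CohortTruth:
    """Ground truth for scoring recovery: who generated each donation."""

    donor_of_donation: list[int]
    snapshot_of_donation: list[DonationPayload | None]
    final_snapshot: dict[int, DonationPayload]
    clean_donors: list[int]
    adversarial_donors: dict[int, str]  # donor -> archetype


def _draw_values(rng: np.random.Generator, category: str, n: int) -> tuple[np.ndarray, list[str]]:
    """Per-category value model; all draws land inside the plausibility
    intervals so that validator rejections isolate adversarial behavior."""
    if category == "resting_heart_rate":
        v = np.clip(np.round(rng.normal(65, 8, n)), 21, 250)
        return v, [""] * n
    if category == "blood_pressure_systolic":
        return np.clip(np.round(rng.normal(125, 15, n)), 60, 260), [""] * n
    if category == "blood_pressure_diastolic":
        return np.clip(np.round(rng.normal(78, 10, n)), 30, 160), [""] * n
    if category == "sleep_duration":
        return np.clip(np.round(rng.normal(7.2, 1.1, n), 2), 0, 24), [""] * n
    if category == "steps":
        v = np.clip(np.round(np.exp(rng.normal(np.log(7000), 0.5, n))), 0, 200000)
        return v, [""] * n
    if category == "lab_result":
        names = list(_LAB_PANEL)
        idx = rng.integers(0, len(names), n)
        analytes = [names[i] for i in idx]
        mu = np.array([_LAB_PANEL[a][0] for a in analytes])
        sd = np.array([_LAB_PANEL[a][1] for a in analytes])
        v = np.round(np.maximum(rng.normal(mu, sd), 0.1), 1)
        return v, analytes
    raise ValueError(category)


def _donor_questionnaire(rng: np.random.Generator) -> tuple[QuestionnaireEntry, ...]:
    entries = []
    for key, answers in DEFAULT_QUESTIONNAIRE_VOCAB.items():
        entries.append(QuestionnaireEntry(key, answers[int(rng.integers(0, len(answers)))]))
    return tuple(entries)


def _accrue_rows(
    rng: np.random.Generator,
    rates: dict[str, float],
    day_lo: int,
    day_hi: int,
) -> list[HealthRecordRow]:
    """New rows accrued on days [day_lo, day_hi) by per-category Poisson draws."""
    rows: list[HealthRecordRow] = []
    ndays = day_hi - day_lo
    if ndays <= 0:
        return rows
    for category in sorted(rates):
        counts = rng.poisson(rates[category], ndays)
        total = int(counts.sum())
        if not total:
            continue
        values, analytes = _draw_values(rng, category, total)
        days = np.repeat(np.arange(day_lo, day_hi), counts)
        for d, v, a in zip(days, values, analytes):
            rows.append(
                HealthRecordRow(
                    category, BASE_DATE + _dt.timedelta(days=int(d)), float(v), a
                )
            )
    return rows


def _mangle(rng: np.random.Generator, kind: str, snapshot: DonationPayload) -> tuple[bytes, DonationPayload | None]:
    """Produce one adversarial plaintext from a clean snapshot."""
    if kind == "garbage":
        return rng.bytes(256), None
    if kind == "bad_schema":
        csv = serialize_csv(snapshot)
        return csv.replace(b"section,", b"sektion,", 1), None
    if kind == "forbidden_field":
        csv = serialize_csv(snapshot)
        lat = round(47 + float(rng.uniform(0, 8)), 4)
        return csv + f"questionnaire,,,,,gps_latitude,{lat}\n".encode(), None
    if kind == "implausible":
        bad_rows = tuple(
            HealthRecordRow(
                "resting_heart_rate",
                BASE_DATE + _dt.timedelta(days=int(d)),
                float(v),
            )
            for d, v in zip(
                rng.integers(0, 300, 5), np.round(rng.uniform(260, 400, 5))
            )
        )
        payload = DonationPayload(
            rows=snapshot.rows + bad_rows, questionnaire=snapshot.questionnaire
        )
        return serialize_csv(payload), payload
    raise ValueError(kind)


def simulate_cohort(config: CohortConfig) -> tuple[list[EmittedDonation], CohortTruth]:
    """Generate the labeled donation stream for one cohort.

    Returns the donations in receipt order (by day, then donor) and the
    ground truth.  Identical configs produce byte-identical streams.
    """
    master = np.random.SeedSequence(config.seed)
    donor_seeds = master.spawn(max(config.n_donors, 1))
    n_adv = int(round(config.adversarial_fraction * config.n_donors))
    adv_donors = {
        d: ADVERSARIAL_ARCHETYPES[i % len(ADVERSARIAL_ARCHETYPES)]
        for i, d in enumerate(range(config.n_donors - n_adv, config.n_donors))
    }

    join_span = max(config.horizon_days - config.period_days - 4, 0)
    pending: list[tuple[int, int, str, bytes, DonationPayload | None]] = []
    final_snapshot: dict[int, DonationPayload] = {}

    for donor in range(config.n_donors):
        rng = np.random.default_rng(donor_seeds[donor])
        if config.n_donors > 1:
            join = round(donor * join_span / (config.n_donors - 1))
        else:
            join = 0
        join = min(join + int(rng.integers(0, 4)), join_span)
        questionnaire = _donor_questionnaire(rng)
        donation_days = list(
            range(join + config.period_days, config.horizon_days, config.period_days)
        )
        rows: list[HealthRecordRow] = []
        prev_count = 0
        last_day = join
        for day in donation_days:
            rows.extend(_accrue_rows(rng, config.records_per_day, last_day, day))
            last_day = day
            if prev_count and config.edit_rate > 0:
                # edit a fraction of the rows that were in the previous
                # snapshot: half deleted, half re-measured (new value)
                n_edit = int(config.edit_rate * prev_count)
                victims = rng.choice(prev_count, size=n_edit, replace=False)
                delete = set(victims[: n_edit // 2].tolist())
                modify = set(victims[n_edit // 2 :].tolist())
                new_rows = []
                for i, r in enumerate(rows):
                    if i in delete:
                        continue
                    if i in modify:
                        v, a = _draw_values(rng, r.category, 1)
                        r = HealthRecordRow(r.category, r.observed_date, float(v[0]), a[0] if r.category == "lab_result" else r.analyte)
                    new_rows.append(r)
                rows = new_rows
            snapshot = DonationPayload(rows=tuple(rows), questionnaire=questionnaire)
            prev_count = len(rows)
            kind = adv_donors.get(donor, "clean")
            if kind == "clean":
                pending.append((day, donor, kind, serialize_csv(snapshot), snapshot))
            else:
                plaintext, payload = _mangle(rng, kind, snapshot)
                pending.append((day, donor, kind, plaintext, payload))
            final_snapshot[donor] = snapshot

    pending.sort(key=lambda t: (t[0], t[1]))  # receipt order: day, then donor
    stream = [
        EmittedDonation(i, donor, day, kind, plaintext, payload)
        for i, (day, donor, kind, plaintext, payload) in enumerate(pending)
    ]
    truth = CohortTruth(
        donor_of_donation=[e.donor for e in stream],
        snapshot_of_donation=[e.payload for e in stream],
        final_snapshot=final_snapshot,
        clean_donors=[d for d in range(config.n_donors) if d not in adv_donors],
        adversarial_donors=adv_donors,
    )
    return stream, truth


def score_recovery(
    stream: list[EmittedDonation],
    truth: CohortTruth,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> dict:
    """Cluster the clean donations offline and score donor recovery."""
    donations = [
        (f"{e.index:06d}", e.payload) for e in stream if e.kind == "clean"
    ]
    clusters = cluster_donations(donations, threshold)
    donor_by_id = {
        f"{e.index:06d}": e.donor for e in stream if e.kind == "clean"
    }
    pure = sum(
        1
        for c in clusters
        if len({donor_by_id[i] for i in c.donation_ids}) == 1
    )
    true_donors = len({e.donor for e in stream if e.kind == "clean"})
    return {
        "clusters_found": len(clusters),
        "true_donors": true_donors,
        "donor_count_error": len(clusters) - true_donors,
        "cluster_purity": pure / len(clusters) if clusters else 1.0,
        "duplicates_merged": len(donations) - len(clusters),
    }


@dataclass
class EndToEndResult:
    """Metrics report plus the run's artifacts for deeper harness assertions."""

    report: dict
    stream: list[EmittedDonation]
    truth: CohortTruth
    observed_envelopes: list[TransferEnvelope]
    store_root: Path | None
    private_key: object | None  # RSAPrivateKey; kept for decrypt-and-compare checks


def run_end_to_end(
    config: CohortConfig,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    workdir: str | Path | None = None,
    modulus_bits: int = 2048,
) -> EndToEndResult:
    """Drive a full loopback run: simulate -> encrypt -> proxy -> database ->
    curation, and score everything against the ground truth.

    The report carries acceptance/rejection counts per stage, recovered donor
    statistics, and the blindness and statelessness audits; the result object
    additionally exposes the wire captures and ground truth for the
    full-donation and decryption checks.
    """
    stream, truth = simulate_cohort(config)
    report = {
        "donations_sent": len(stream),
        "accepted": 0,
        "rejected_by_stage": {},
        "curation_flagged": 0,
        "clusters_found": 0,
        "true_donors": len({e.donor for e in stream if e.kind == "clean"}),
        "donor_count_error": 0,
        "cluster_purity": 1.0,
        "blindness_audit": True,
        "statelessness_audit": True,
    }
    if not stream:
        report["donor_count_error"] = 0
        return EndToEndResult(report, stream, truth, [], None, None)

    root = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="anodon-e2e-"))
    rng_master = random.Random(config.seed)
    keypair = generate_keypair(modulus_bits, random.Random(rng_master.randrange(2**31)))
    store = DonationStore(root / "store")
    server = DonationServer(store, keypair.private_key)
    proxy = ProxyServer(upstream_url=server.url, storage_root=root / "proxy-spool")
    observed: list[TransferEnvelope] = []
    statuses: list[Status] = []
    with server, proxy:
        inner = client_mod.http_transport(proxy.url)

        def transport(body: bytes):  # wire capture for the audits
            observed.append(TransferEnvelope.parse(body))
            return inner(body)

        for e in stream:
            rng = random.Random(rng_master.randrange(2**31))
            if e.kind == "clean":
                state = client_mod.give_consent(
                    _dt.datetime(2024, 1, 1, tzinfo=_dt.timezone.utc)
                )
                resp, _ = client_mod.donate(
                    e.payload, keypair.public_key, transport, state, rng
                )
            else:
                env = TransferEnvelope.from_envelope(
                    encrypt(e.plaintext, keypair.public_key, rng)
                )
                resp = transport(env.to_json())
            statuses.append(resp.status)
        server_records = store.records()
        blindness = audit_blindness(
            list(proxy.access_log) + list(proxy.forward_log), observed
        )
        outbound = {r.outbound_address for r in proxy.forward_log if r.outbound_address}
        origins_ok = all(
            rec.origin_address in outbound for rec in server_records
        )
        report["blindness_audit"] = bool(blindness and origins_ok)
    report["statelessness_audit"] = assert_stateless(proxy.storage_root)

    report["accepted"] = sum(1 for s in statuses if s is Status.OK)
    for s in statuses:
        if s is not Status.OK:
            report["rejected_by_stage"][s.value] = (
                report["rejected_by_stage"].get(s.value, 0) + 1
            )

    # curation: plausibility-screen accepted donations, then cluster survivors
    exported = export_donations(store)
    # receipt order at the server equals send order (sequential sends)
    index_of_record = {rec.donation_id: i for i, rec in enumerate(store.records())}
    survivors = []
    flagged = 0
    flagged_stream_idx = set()
    for donation_id, payload in exported:
        _, rejections = plausibility_filter(payload)
        if rejections:
            flagged += 1
            flagged_stream_idx.add(index_of_record[donation_id])
        else:
            survivors.append((donation_id, payload))
    report["curation_flagged"] = flagged

    # label-vs-outcome cross-check: a donation counts as rejected if the
    # server refused it or curation flagged implausible content
    adv_total = adv_rejected = clean_total = clean_rejected = 0
    for e in stream:
        rejected = statuses[e.index] is not Status.OK or e.index in flagged_stream_idx
        if e.kind == "clean":
            clean_total += 1
            clean_rejected += rejected
        else:
            adv_total += 1
            adv_rejected += rejected
    report["adversarial_donations"] = adv_total
    report["adversarial_rejected"] = adv_rejected
    report["clean_donations"] = clean_total
    report["clean_rejected"] = clean_rejected

    clusters = cluster_donations(survivors, threshold)
    donor_by_id = {
        donation_id: truth.donor_of_donation[index_of_record[donation_id]]
        for donation_id, _ in survivors
    }
    pure = sum(
        1 for c in clusters if len({donor_by_id[i] for i in c.donation_ids}) == 1
    )
    report["clusters_found"] = len(clusters)
    report["donor_count_error"] = len(clusters) - report["true_donors"]
    report["cluster_purity"] = pure / len(clusters) if clusters else 1.0
    return EndToEndResult(
        report, stream, truth, observed, root / "store", keypair.private_key
    )
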