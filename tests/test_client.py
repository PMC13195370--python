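"""Donation scheduler: cadence, reminder window, opt-out, retry, screening."""

import datetime as dt
import random

import pytest

from anodon.client import (
    DonationScheduleState,
    ScheduleConfig,
    ScreeningFailure,
    Status,
    donate,
    give_consent,
    next_donation_due,
    opt_out,
    reminder_due,
    retry_due,
)
from anodon.envelope import decrypt
from anodon.payload import DonationPayload, HealthRecordRow, serialize_csv
from anodon.wire import DonationResponse, TransferEnvelope
from .conftest import random_payload

UTC = dt.timezone.utc
CONSENT = dt.datetime(2024, 1, 1, 12, 0, tzinfo=UTC)
CONFIG = ScheduleConfig()


def ok_transport(body: bytes) -> DonationResponse:
    return DonationResponse(Status.OK)


class TestDueDates:
    def test_no_consent_means_never(self):
        state = opt_out(give_consent(CONSENT))
        assert next_donation_due(state, CONFIG, CONSENT) is None

    def test_anchored_to_last_successful_donation(self):
        state = DonationScheduleState(
            consent_given=True,
            consented_at=CONSENT,
            last_donation_at=dt.datetime(2024, 1, 1, tzinfo=UTC),
        )
        assert next_donation_due(state, CONFIG, CONSENT) == dt.datetime(
            2024, 3, 31, tzinfo=UTC
        )

    def test_first_donation_one_period_after_consent(self):
        state = give_consent(CONSENT)
        assert next_donation_due(state, CONFIG, CONSENT) == CONSENT + dt.timedelta(days=90)


class TestReminder:
    def test_window_boundaries(self):
        state = give_consent(CONSENT)
        due = next_donation_due(state, CONFIG, CONSENT)
        assert reminder_due(state, CONFIG, due - dt.timedelta(hours=24))
        assert not reminder_due(state, CONFIG, due - dt.timedelta(hours=25))
        assert reminder_due(state, CONFIG, due - dt.timedelta(hours=1))
        assert not reminder_due(state, CONFIG, due)

    def test_withdrawing_consent_silences_reminder_and_donation(self):
        state = give_consent(CONSENT)
        due = next_donation_due(state, CONFIG, CONSENT)
        state = opt_out(state)  # withdrawn 12h before due
        assert not reminder_due(state, CONFIG, due - dt.timedelta(hours=12))
        assert next_donation_due(state, CONFIG, due) is None


def walk_one_year(state, pub, transport, start=CONSENT, days=365):
    """Hourly clock walk; donate a fresh empty snapshot whenever due."""
    donated = []
    now = start
    end = start + dt.timedelta(days=days)
    while now < end:
        due = next_donation_due(state, CONFIG, now)
        if due is not None and now >= due:
            resp, state = donate(
                DonationPayload(), pub, transport, state,
                random.Random(len(donated)), now=now,
            )
            if resp.status is Status.OK:
                donated.append(now)
        now += dt.timedelta(hours=1)
    return donated, state


class TestYearWalk:
    def test_uninterrupted_year_emits_four_donations(self, keypair):
        """Day-by-day enumeration over 365 days with period 90: donations on
        days 90, 180, 270 and 360 after consent — exactly four."""
        donated, _ = walk_one_year(
            give_consent(CONSENT), keypair.public_key, ok_transport
        )
        assert len(donated) == 4
        assert [(d - CONSENT).days for d in donated] == [90, 180, 270, 360]

    def test_reminders_fire_exactly_in_the_24h_window(self, keypair):
        state = give_consent(CONSENT)
        reminder_hours = []
        donations = []
        now = CONSENT
        while now < CONSENT + dt.timedelta(days=95):
            if reminder_due(state, CONFIG, now):
                reminder_hours.append(now)
            due = next_donation_due(state, CONFIG, now)
            if due is not None and now >= due:
                _, state = donate(
                    DonationPayload(), keypair.public_key, ok_transport, state,
                    random.Random(0), now=now,
                )
                donations.append(now)
            now += dt.timedelta(hours=1)
        due0 = CONSENT + dt.timedelta(days=90)
        assert donations == [due0]
        assert reminder_hours == [
            due0 - dt.timedelta(hours=h) for h in range(24, 0, -1)
        ]

    def test_opt_out_stops_all_future_donations(self, keypair):
        state = give_consent(CONSENT)
        _, state = donate(
            DonationPayload(), keypair.public_key, ok_transport, state,
            random.Random(0), now=CONSENT + dt.timedelta(days=90),
        )
        state = opt_out(state)
        donated, _ = walk_one_year(state, keypair.public_key, ok_transport)
        assert donated == []
        assert opt_out(state) == state  # idempotent


class TestRetry:
    def test_failure_queues_retry_then_backoff_governs_reattempt(self, keypair):
        def failing(body):
            return DonationResponse(Status.ERR_UPSTREAM_UNAVAILABLE)

        state = give_consent(CONSENT)
        t0 = CONSENT + dt.timedelta(days=90)
        resp, state = donate(
            DonationPayload(), keypair.public_key, failing, state,
            random.Random(1), now=t0,
        )
        assert resp.status is Status.ERR_UPSTREAM_UNAVAILABLE
        assert state.pending_retry and state.retry_attempts == 1
        assert state.last_donation_at is None  # not a success
        assert not retry_due(state, CONFIG, t0 + dt.timedelta(minutes=30))
        assert retry_due(state, CONFIG, t0 + dt.timedelta(hours=1))
        # second failure backs off 6h
        _, state = donate(
            DonationPayload(), keypair.public_key, failing, state,
            random.Random(2), now=t0 + dt.timedelta(hours=1),
        )
        assert state.retry_attempts == 2
        assert not retry_due(state, CONFIG, t0 + dt.timedelta(hours=4))
        assert retry_due(state, CONFIG, t0 + dt.timedelta(hours=7))
        # success clears the queue
        _, state = donate(
            DonationPayload(), keypair.public_key, ok_transport, state,
            random.Random(3), now=t0 + dt.timedelta(hours=7),
        )
        assert not state.pending_retry and state.retry_attempts == 0

    def test_retry_resends_current_snapshot_not_cached_payload(self, keypair):
        """A retry re-snapshots the full dataset: what arrives after a retry
        is the dataset at retry time, not the one that failed."""
        captured = []
        fail_first = {"n": 0}

        def flaky(body):
            fail_first["n"] += 1
            if fail_first["n"] == 1:
                return DonationResponse(Status.ERR_UPSTREAM_UNAVAILABLE)
            captured.append(body)
            return DonationResponse(Status.OK)

        grown = DonationPayload(
            rows=(HealthRecordRow("steps", dt.date(2024, 3, 1), 512.0),)
        )
        state = give_consent(CONSENT)
        _, state = donate(DonationPayload(), keypair.public_key, flaky, state,
                          random.Random(4), now=CONSENT)
        _, state = donate(grown, keypair.public_key, flaky, state,
                          random.Random(5), now=CONSENT + dt.timedelta(hours=1))
        assert len(captured) == 1
        env = TransferEnvelope.parse(captured[0]).to_envelope()
        assert decrypt(env, keypair.private_key) == serialize_csv(grown)


class TestScreeningGate:
    def test_forbidden_field_sends_no_traffic(self, keypair):
        calls = []

        def counting(body):
            calls.append(body)
            return DonationResponse(Status.OK)

        tainted = DonationPayload(
            rows=(HealthRecordRow("lab_result", dt.date(2024, 1, 1), 1.0, "gps_longitude"),)
        )
        state = give_consent(CONSENT)
        with pytest.raises(ScreeningFailure):
            donate(tainted, keypair.public_key, counting, state, random.Random(6))
        assert calls == []  # packet count zero

    def test_transmitted_payload_equals_full_snapshot(self, keypair):
        captured = []

        def capture(body):
            captured.append(body)
            return DonationResponse(Status.OK)

        snapshot = random_payload(random.Random(7))
        donate(snapshot, keypair.public_key, capture, give_consent(CONSENT),
               random.Random(8))
        env = TransferEnvelope.parse(captured[0]).to_envelope()
        assert decrypt(env, keypair.private_key) == serialize_csv(snapshot)


class TestStatePersistence:
    def test_json_roundtrip(self, tmp_path):
        state = DonationScheduleState(
            consent_given=True,
            consented_at=CONSENT,
            last_donation_at=CONSENT + dt.timedelta(days=90),
            last_attempt_at=CONSENT + dt.timedelta(days=90),
            pending_retry=True,
            retry_attempts=2,
        )
        path = tmp_path / "state.json"
        state.save(path)
        assert DonationScheduleState.load(path) == state

    def test_retry_invariant_enforced(self):
        with pytest.raises(ValueError):
            DonationScheduleState(consent_given=True, retry_attempts=3)
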