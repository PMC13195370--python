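"""Donation scheduler and sender.

The client keeps only consent state and transmission timestamps.  While
consent holds, it donates the donor's complete current dataset once per
period (default 90 days — the concrete reading of a quarterly cadence),
with a reminder raised 24 hours before each donation so the donor can still
opt out.  The first donation falls one full period after consent; afterwards
the cadence is anchored to the last successful donation.

Failed transmissions are queued for retry with increasing backoff.  A retry
never replays the failed payload: the client re-snapshots the complete
current dataset at send time, preserving the full-donation contract (there
is no identifier that could link partial donations).

Opting out stops all future donations but cannot recall anything already
donated: anonymized data cannot be selected for deletion because no link
between a person and a dataset exists.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import http.client
import json
import random
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable
from urllib.parse import urlsplit

from .crypto.rsa import RSAPublicKey
from .envelope import encrypt
from .payload import DonationPayload, ForbiddenFieldPolicy, screen_identifiers, serialize_csv
from .wire import DonationResponse, Status, TransferEnvelope

#: send retries at these delays (hours) after consecutive failures, then daily
DEFAULT_RETRY_BACKOFF_HOURS = (1, 6, 24)


class ScreeningFailure(ValueError):
    """Snapshot contains a policy-forbidden field; donation aborted locally."""


@dataclass(frozen=True)
class ScheduleConfig:
    period_days: int = 90
    reminder_lead_hours: int = 24
    retry_backoff_hours: tuple[int, ...] = DEFAULT_RETRY_BACKOFF_HOURS

    def __post_init__(self):
        if self.period_days <= 0:
            raise ValueError("period_days must be positive")
        if not self.reminder_lead_hours < self.period_days * 24:
            raise ValueError("reminder lead must be shorter than the period")


@dataclass(frozen=True)
class DonationScheduleState:
    """Everything the client remembers: consent plus bare timestamps."""

    consent_given: bool
    consented_at: _dt.datetime | None = None
    last_donation_at: _dt.datetime | None = None
    last_attempt_at: _dt.datetime | None = None
    pending_retry: bool = False
    retry_attempts: int = 0

    def __post_init__(self):
        if not self.pending_retry and self.retry_attempts != 0:
            raise ValueError("retry_attempts must be 0 when no retry is pending")

    # -- persistence ---------------------------------------------------
    def to_json(self) -> str:
        def ts(v):
            return v.isoformat() if v else None

        return json.dumps(
            {
                "consent_given": self.consent_given,
                "consented_at": ts(self.consented_at),
                "last_donation_at": ts(self.last_donation_at),
                "last_attempt_at": ts(self.last_attempt_at),
                "pending_retry": self.pending_retry,
                "retry_attempts": self.retry_attempts,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DonationScheduleState":
        doc = json.loads(text)

        def ts(v):
            return _dt.datetime.fromisoformat(v) if v else None

        return cls(
            consent_given=doc["consent_given"],
            consented_at=ts(doc.get("consented_at")),
            last_donation_at=ts(doc.get("last_donation_at")),
            last_attempt_at=ts(doc.get("last_attempt_at")),
            pending_retry=doc.get("pending_retry", False),
            retry_attempts=doc.get("retry_attempts", 0),
        )

    def save(self, path: str | Path):
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "DonationScheduleState":
        return cls.from_json(Path(path).read_text())


def give_consent(now: _dt.datetime) -> DonationScheduleState:
    return DonationScheduleState(consent_given=True, consented_at=now)


def next_donation_due(
    state: DonationScheduleState, config: ScheduleConfig, now: _dt.datetime
) -> _dt.datetime | None:
    """When the next scheduled donation is due; ``None`` if consent withdrawn.

    The anchor is the last successful donation, or the consent time for the
    first donation — one full period of data accrues before anything is sent,
    which also gives the pre-donation reminder a window to act in.
    """
    if not state.consent_given:
        return None
    anchor = state.last_donation_at or state.consented_at
    if anchor is None:
        return None
    return anchor + _dt.timedelta(days=config.period_days)


def reminder_due(
    state: DonationScheduleState, config: ScheduleConfig, now: _dt.datetime
) -> bool:
    """True iff ``now`` lies in the [due - lead, due) reminder window."""
    due = next_donation_due(state, config, now)
    if due is None:
        return False
    return due - _dt.timedelta(hours=config.reminder_lead_hours) <= now < due


def retry_due(
    state: DonationScheduleState, config: ScheduleConfig, now: _dt.datetime
) -> bool:
    """True iff a failed donation should be reattempted at ``now``."""
    if not (state.consent_given and state.pending_retry and state.last_attempt_at):
        return False
    backoff = config.retry_backoff_hours
    idx = min(state.retry_attempts - 1, len(backoff) - 1)
    delay = backoff[idx] if state.retry_attempts <= len(backoff) else 24
    return now >= state.last_attempt_at + _dt.timedelta(hours=delay)


def opt_out(state: DonationScheduleState) -> DonationScheduleState:
    """Withdraw consent.  Idempotent; already-donated anonymized data cannot
    be deleted, so no deletion request exists or is sent."""
    return replace(state, consent_given=False, pending_retry=False, retry_attempts=0)


Transport = Callable[[bytes], DonationResponse]


def http_transport(proxy_url: str) -> Transport:
    """POST bodies to ``<proxy_url>/donate`` and decode the JSON reply."""
    parts = urlsplit(proxy_url)

    def send(body: bytes) -> DonationResponse:
        conn = http.client.HTTPConnection(parts.hostname, parts.port, timeout=30)
        try:
            conn.request(
                "POST", "/donate", body, {"Content-Type": "application/json"}
            )
            resp = conn.getresponse()
            return DonationResponse.from_json(resp.read())
        except (OSError, http.client.HTTPException):
            return DonationResponse(Status.ERR_UPSTREAM_UNAVAILABLE)
        finally:
            conn.close()

    return send


def donate(
    snapshot: DonationPayload,
    public_key: RSAPublicKey,
    transport: Transport | str,
    state: DonationScheduleState,
    rng: random.Random | None = None,
    now: _dt.datetime | None = None,
    policy: ForbiddenFieldPolicy | None = None,
) -> tuple[DonationResponse, DonationScheduleState]:
    """Screen, serialize, encrypt and send one full snapshot.

    If screening finds any forbidden field the donation aborts locally —
    the transport is never invoked.  On success the schedule advances; on
    any transmitted error a retry is queued, but the snapshot itself is not
    cached: the retry will re-snapshot the complete current dataset.
    """
    if not state.consent_given:
        raise ValueError("cannot donate without consent")
    now = now or _dt.datetime.now(_dt.timezone.utc)
    report = screen_identifiers(snapshot, policy)
    if not report.passed:
        names = ", ".join(v.name for v in report.violations)
        raise ScreeningFailure(f"forbidden fields in snapshot: {names}")
    env = encrypt(serialize_csv(snapshot), public_key, rng)
    body = TransferEnvelope.from_envelope(env).to_json()
    send = http_transport(transport) if isinstance(transport, str) else transport
    response = send(body)
    if response.status is Status.OK:
        new_state = replace(
            state,
            last_donation_at=now,
            last_attempt_at=now,
            pending_retry=False,
            retry_attempts=0,
        )
    else:
        new_state = replace(
            state,
            last_attempt_at=now,
            pending_retry=True,
            retry_attempts=state.retry_attempts + 1,
        )
    return response, new_state
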