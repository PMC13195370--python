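"""Loopback integration of proxy and donation database."""

import hashlib
import http.client
import json
import random

import pytest

from anodon.client import http_transport
from anodon.envelope import encrypt
from anodon.payload import parse_csv, serialize_csv
from anodon.proxy import (
    ForwardOutcome,
    ProxyLogEntry,
    ProxyServer,
    assert_stateless,
    audit_blindness,
)
from anodon.server import (
    DonationServer,
    DonationStatus,
    DonationStore,
    export_donations,
)
from anodon.wire import Status, TransferEnvelope
from .conftest import random_payload


@pytest.fixture
def stack(tmp_path, keypair):
    """A running donation database behind a running proxy."""
    store = DonationStore(tmp_path / "store")
    server = DonationServer(store, keypair.private_key)
    with server:
        proxy = ProxyServer(upstream_url=server.url, storage_root=tmp_path / "spool")
        with proxy:
            yield store, server, proxy


def _envelope_body(keypair, rng, payload=None):
    blob = serialize_csv(payload if payload is not None else random_payload(rng))
    env = encrypt(blob, keypair.public_key, rng)
    return TransferEnvelope.from_envelope(env).to_json(), blob


class TestForwarding:
    def test_body_forwarded_byte_identically(self, stack, keypair):
        store, server, proxy = stack
        body, blob = _envelope_body(keypair, random.Random(1))
        resp = http_transport(proxy.url)(body)
        assert resp.status is Status.OK
        records = store.records()
        assert len(records) == 1
        stored = (store.root / records[0].ciphertext_path).read_bytes()
        assert hashlib.sha256(stored).digest() == hashlib.sha256(body).digest()
        assert (store.root / records[0].plaintext_path).read_bytes() == blob

    def test_upstream_down_relays_unavailable_and_keeps_nothing(self, tmp_path, keypair):
        proxy = ProxyServer(
            upstream_url="http://127.0.0.1:9", storage_root=tmp_path / "spool"
        )
        body, _ = _envelope_body(keypair, random.Random(2))
        with proxy:
            resp = http_transport(proxy.url)(body)
        assert resp.status is Status.ERR_UPSTREAM_UNAVAILABLE
        assert proxy.forward_log[-1].outcome is ForwardOutcome.UPSTREAM_ERROR
        assert assert_stateless(proxy.storage_root)

    def test_malformed_envelope_rejected_without_upstream_call(self, stack):
        store, server, proxy = stack
        bad = json.dumps(
            {"version": 1, "c1_b64": "AAAA", "c2_b64": "!!not-base64!!"}
        ).encode()
        resp = http_transport(proxy.url)(bad)
        assert resp.status is Status.ERR_MALFORMED_ENVELOPE
        assert proxy.forward_log[-1].outcome is ForwardOutcome.MALFORMED_REQUEST
        assert store.records() == []  # never reached the database

    def test_origin_seen_by_database_is_the_proxy(self, stack, keypair):
        """The database's TCP peer is the proxy's outbound socket, never the
        client's; the client's socket address appears only in the proxy's
        access log."""
        store, server, proxy = stack
        body, _ = _envelope_body(keypair, random.Random(3))
        conn = http.client.HTTPConnection(*proxy.address, timeout=10)
        conn.request("POST", "/donate", body, {"Content-Type": "application/json"})
        client_local = "%s:%d" % conn.sock.getsockname()[:2]
        conn.getresponse().read()
        conn.close()
        outbound = {r.outbound_address for r in proxy.forward_log}
        for rec in store.records():
            assert rec.origin_address in outbound
            assert rec.origin_address != client_local
        assert any(e.client_address == client_local for e in proxy.access_log)


class TestBlindnessAudit:
    def test_compliant_run_is_blind(self, stack, keypair):
        store, server, proxy = stack
        rng = random.Random(4)
        observed = []
        send = http_transport(proxy.url)
        for _ in range(10):
            body, _ = _envelope_body(keypair, rng)
            observed.append(TransferEnvelope.parse(body))
            send(body)
        logs = list(proxy.access_log) + list(proxy.forward_log)
        assert audit_blindness(logs, observed)

    def test_leaky_logger_is_caught(self, keypair):
        env = TransferEnvelope.from_envelope(
            encrypt(b"secret donation", keypair.public_key, random.Random(5))
        )
        leaky = ProxyLogEntry(
            timestamp="t", client_address="1.2.3.4:5",
            outcome=ForwardOutcome.FORWARDED_OK, payload_size=0,
        )
        echoing = {"note": "debug: " + env.c1_b64[:40]}
        assert audit_blindness([leaky], [env])
        assert not audit_blindness([leaky, echoing], [env])

    def test_empty_log_is_blind(self, keypair):
        env = TransferEnvelope.from_envelope(
            encrypt(b"x", keypair.public_key, random.Random(6))
        )
        assert audit_blindness([], [env])


class TestStatelessness:
    def test_fresh_proxy_zero_traffic(self, tmp_path):
        proxy = ProxyServer("http://127.0.0.1:9", tmp_path / "spool")
        assert assert_stateless(proxy.storage_root)

    def test_after_successes_and_failures(self, stack, keypair):
        store, server, proxy = stack
        rng = random.Random(7)
        send = http_transport(proxy.url)
        for _ in range(20):
            send(_envelope_body(keypair, rng)[0])
        send(b"not an envelope at all")
        assert assert_stateless(proxy.storage_root)

    def test_after_upstream_failures(self, tmp_path, keypair):
        proxy = ProxyServer("http://127.0.0.1:9", tmp_path / "spool")
        with proxy:
            send = http_transport(proxy.url)
            for _ in range(20):
                send(_envelope_body(keypair, random.Random(8))[0])
        assert assert_stateless(proxy.storage_root)


class TestServerPipeline:
    def test_happy_path_roundtrips(self, tmp_path, keypair):
        store = DonationStore(tmp_path / "s")
        payload = random_payload(random.Random(9))
        body, blob = _envelope_body(keypair, random.Random(9), payload)
        resp = store.receive(body, keypair.private_key)
        assert resp.status is Status.OK
        rec = store.records()[0]
        assert rec.status is DonationStatus.DECRYPTED_OK
        assert parse_csv((store.root / rec.plaintext_path).read_bytes()) == payload

    def test_tampered_key_keeps_ciphertext_only(self, tmp_path, keypair):
        store = DonationStore(tmp_path / "s")
        body, _ = _envelope_body(keypair, random.Random(10))
        env = TransferEnvelope.parse(body)
        c2 = bytearray(env.to_envelope().c2)
        c2[50] ^= 1
        import base64

        tampered = TransferEnvelope(
            version=env.version,
            c1_b64=env.c1_b64,
            c2_b64=base64.b64encode(bytes(c2)).decode(),
        ).to_json()
        resp = store.receive(tampered, keypair.private_key)
        assert resp.status is Status.ERR_DECRYPT_KEY
        rec = store.records()[0]
        assert rec.status is DonationStatus.FAILED_KEY
        assert (store.root / rec.ciphertext_path).exists()
        assert rec.plaintext_path is None

    def test_unknown_category_yields_schema_error(self, tmp_path, keypair):
        """Payloads failing CSV schema validation are rejected."""
        store = DonationStore(tmp_path / "s")
        bad_csv = (
            b"section,category,observed_date,value,analyte,key,answer\n"
            b"health,unknown_thing,2024-01-01,1,,,\n"
        )
        env = encrypt(bad_csv, keypair.public_key, random.Random(11))
        resp = store.receive(
            TransferEnvelope.from_envelope(env).to_json(), keypair.private_key
        )
        assert resp.status is Status.ERR_SCHEMA
        assert store.records()[0].status is DonationStatus.FAILED_SCHEMA

    def test_failure_isolation_and_export_order(self, tmp_path, keypair):
        store = DonationStore(tmp_path / "s")
        rng = random.Random(12)
        sent_payloads = []
        for i in range(13):
            if i % 4 == 3:  # inject 3 failing donations between good ones
                bad = encrypt(b"garbage bytes \xff", keypair.public_key, rng)
                store.receive(
                    TransferEnvelope.from_envelope(bad).to_json(), keypair.private_key
                )
            else:
                p = random_payload(rng)
                sent_payloads.append(p)
                body, _ = _envelope_body(keypair, rng, p)
                assert store.receive(body, keypair.private_key).status is Status.OK
        exported = export_donations(store)
        assert [p for _, p in exported] == sent_payloads
        # receipt order survives a restart (fresh handle over the same root)
        reopened = export_donations(DonationStore(store.root))
        assert [i for i, _ in reopened] == [i for i, _ in exported]

    def test_empty_store_exports_nothing(self, tmp_path):
        assert export_donations(DonationStore(tmp_path / "s")) == []

    def test_records_carry_no_identity_fields(self, tmp_path, keypair):
        store = DonationStore(tmp_path / "s")
        body, _ = _envelope_body(keypair, random.Random(13))
        store.receive(body, keypair.private_key, origin_address="10.0.0.2:999")
        raw = json.loads((store.root / "index.jsonl").read_text())
        assert set(raw) == {
            "donation_id", "received_at", "ciphertext_path",
            "plaintext_path", "status", "origin_address",
        }
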