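"""The donation database service.

Receives transfer envelopes (normally via the proxy), and processes each one
in a fixed order: store the ciphertext at rest, decapsulate the symmetric
key with sk_D, decrypt the payload, validate the CSV schema, store the
plaintext.  The reply status names the first failing stage, so a client can
distinguish a tampered key encapsulation from a tampered payload from a
schema-invalid donation.

Ciphertext is retained even when a later stage fails (forensic
reprocessing); plaintext exists on disk only for fully validated donations.
Stored records carry no donor identity and no client network address — the
``origin_address`` field records the TCP peer (the proxy, in any compliant
deployment) purely so integration tests can assert the blindness property.

Store layout:  ``DIR/ciphertext/<id>.bin``, ``DIR/plaintext/<id>.csv``,
``DIR/index.jsonl`` (one JSON record per donation, receipt order).
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import threading
from dataclasses import asdict, dataclass
from enum import Enum
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

from . import payload as payload_mod
from .crypto.rsa import RSAPrivateKey
from .envelope import KeyDecapsulationError, PayloadDecryptionError, decrypt
from .payload import DonationPayload, SchemaError
from .wire import DonationResponse, MalformedEnvelope, Status, TransferEnvelope


class DonationStatus(str, Enum):
    STORED_ENCRYPTED = "STORED_ENCRYPTED"
    DECRYPTED_OK = "DECRYPTED_OK"
    FAILED_KEY = "FAILED_KEY"
    FAILED_DATA = "FAILED_DATA"
    FAILED_SCHEMA = "FAILED_SCHEMA"


@dataclass(frozen=True)
class StoredDonation:
    """Index record for one received donation; no donor identity by design."""

    donation_id: str
    received_at: str
    ciphertext_path: str
    plaintext_path: str | None
    status: DonationStatus
    origin_address: str


_STATUS_TO_RESPONSE = {
    DonationStatus.DECRYPTED_OK: Status.OK,
    DonationStatus.FAILED_KEY: Status.ERR_DECRYPT_KEY,
    DonationStatus.FAILED_DATA: Status.ERR_DECRYPT_DATA,
    DonationStatus.FAILED_SCHEMA: Status.ERR_SCHEMA,
}


class DonationStore:
    """Filesystem-backed store of received donations, in receipt order."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        (self.root / "ciphertext").mkdir(parents=True, exist_ok=True)
        (self.root / "plaintext").mkdir(parents=True, exist_ok=True)
        self._index_path = self.root / "index.jsonl"
        self._lock = threading.Lock()
        self._seq = sum(1 for _ in self._iter_index())

    def _iter_index(self):
        if not self._index_path.exists():
            return
        with self._index_path.open() as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    rec["status"] = DonationStatus(rec["status"])
                    yield StoredDonation(**rec)

    def records(self) -> list[StoredDonation]:
        return list(self._iter_index())

    def _new_id(self) -> str:
        # counter + random suffix: never derived from payload content, so the
        # operator cannot link identical re-donations outside the curation stage
        self._seq += 1
        return f"{self._seq:06d}-{os.urandom(4).hex()}"

    def receive(
        self,
        body: bytes,
        private_key: RSAPrivateKey,
        origin_address: str = "",
    ) -> DonationResponse:
        """Run the full pipeline on one raw request body.

        Order: structural parse -> store ciphertext -> decapsulate key ->
        decrypt payload -> CSV schema validation -> store plaintext.  The
        response reflects the first failing stage; a failing donation never
        affects any other donation.
        """
        try:
            transfer = TransferEnvelope.parse(body)
        except MalformedEnvelope:
            return DonationResponse(Status.ERR_MALFORMED_ENVELOPE)

        with self._lock:
            donation_id = self._new_id()
            ct_path = self.root / "ciphertext" / f"{donation_id}.bin"
            ct_path.write_bytes(body)
            status = DonationStatus.STORED_ENCRYPTED
            pt_path: Path | None = None
            try:
                plaintext = decrypt(transfer.to_envelope(), private_key)
            except KeyDecapsulationError:
                status = DonationStatus.FAILED_KEY
            except PayloadDecryptionError:
                status = DonationStatus.FAILED_DATA
            else:
                try:
                    payload_mod.parse_csv(plaintext)
                except SchemaError:
                    status = DonationStatus.FAILED_SCHEMA
                else:
                    pt_path = self.root / "plaintext" / f"{donation_id}.csv"
                    pt_path.write_bytes(plaintext)
                    status = DonationStatus.DECRYPTED_OK
            record = StoredDonation(
                donation_id=donation_id,
                received_at=_dt.datetime.now(_dt.timezone.utc).isoformat(),
                ciphertext_path=str(ct_path.relative_to(self.root)),
                plaintext_path=str(pt_path.relative_to(self.root)) if pt_path else None,
                status=status,
                origin_address=origin_address,
            )
            with self._index_path.open("a") as fh:
                rec = asdict(record)
                rec["status"] = record.status.value
                fh.write(json.dumps(rec) + "\n")
        return DonationResponse(_STATUS_TO_RESPONSE[status])


def export_donations(store: str | Path | DonationStore) -> list[tuple[str, DonationPayload]]:
    """All fully validated donations, parsed, in receipt order.

    Receipt order is the persisted index order, so it survives restarts.
    """
    st = store if isinstance(store, DonationStore) else DonationStore(store)
    out: list[tuple[str, DonationPayload]] = []
    for rec in st.records():
        if rec.status is DonationStatus.DECRYPTED_OK and rec.plaintext_path:
            data = (st.root / rec.plaintext_path).read_bytes()
            out.append((rec.donation_id, payload_mod.parse_csv(data)))
    return out


class _ServerHandler(BaseHTTPRequestHandler):
    protocol_version = "HTTP/1.1"

    def log_message(self, *args):
        pass

    def do_POST(self):
        srv: DonationServer = self.server  # type: ignore[assignment]
        if self.path != "/donate":
            body = DonationResponse(Status.ERR_MALFORMED_ENVELOPE).to_json()
            self._reply(404, body)
            return
        length = int(self.headers.get("Content-Length", 0))
        body = self.rfile.read(length)
        origin = f"{self.client_address[0]}:{self.client_address[1]}"
        resp = srv.handle_donation(body, origin)  # type: ignore[attr-defined]
        self._reply(200, resp.to_json())

    def _reply(self, code: int, body: bytes):
        self.send_response(code)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)


class DonationServer:
    """Loopback HTTP frontend over a :class:`DonationStore`."""

    def __init__(
        self,
        store: DonationStore,
        private_key: RSAPrivateKey,
        listen: tuple[str, int] = ("127.0.0.1", 0),
    ):
        self.store = store
        self._private_key = private_key
        self.origin_addresses: list[str] = []  # TCP peers, for harness assertions
        self._httpd = ThreadingHTTPServer(listen, _ServerHandler)
        self._httpd.handle_donation = self.handle_donation  # type: ignore[attr-defined]
        self._thread: threading.Thread | None = None

    def handle_donation(self, body: bytes, origin: str) -> DonationResponse:
        self.origin_addresses.append(origin)
        return self.store.receive(body, self._private_key, origin_address=origin)

    @property
    def address(self) -> tuple[str, int]:
        return self._httpd.server_address[:2]

    @property
    def url(self) -> str:
        host, port = self.address
        return f"http://{host}:{port}"

    def start(self):
        self._thread = threading.Thread(target=self._httpd.serve_forever, daemon=True)
        self._thread.start()

    def stop(self):
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread:
            self._thread.join(timeout=5)

    def __enter__(self):
        self.start()
        return self

    def __exit__(self, *exc):
        self.stop()
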