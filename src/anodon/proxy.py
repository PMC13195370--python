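"""The blinded deidentification proxy.

The proxy accepts transfer envelopes from clients and forwards them —
byte-identically — to the donation database over a connection that
originates from the proxy's own address, then relays the database's reply
back to the client.  It is the only component that ever observes a client
network address, and it cannot decrypt anything: this module has no
dependency on private-key material, which the test suite asserts statically.

Nothing is retained: requests are buffered in memory only and released when
the transaction completes, whatever the outcome.  The ``storage_root``
directory exists purely so the statelessness contract is auditable — the
proxy never writes into it.

Client addresses are recorded in an access-log stream that is kept separate
from the forwarding log, mirroring the legal separation between routing
metadata and donation traffic.
"""

from __future__ import annotations

import datetime as _dt
import http.client
import json
import threading
from dataclasses import dataclass, field
from enum import Enum
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import urlsplit

from .wire import DonationResponse, MalformedEnvelope, Status, TransferEnvelope


class ForwardOutcome(str, Enum):
    FORWARDED_OK = "FORWARDED_OK"
    UPSTREAM_ERROR = "UPSTREAM_ERROR"
    MALFORMED_REQUEST = "MALFORMED_REQUEST"


@dataclass(frozen=True)
class ProxyLogEntry:
    """One access-log line: who connected, what happened, how many bytes.

    Never contains envelope bytes or any fragment of c1/c2 — the audit in
    :func:`audit_blindness` enforces this on every run.
    """

    timestamp: str
    client_address: str
    outcome: ForwardOutcome
    payload_size: int


@dataclass
class ForwardRecord:
    """Forwarding-log line: transaction outcome plus the proxy's own outbound
    address (useful for asserting what the upstream observed); deliberately
    carries no client address."""

    timestamp: str
    outcome: ForwardOutcome
    payload_size: int
    outbound_address: str = ""


class _ProxyHandler(BaseHTTPRequestHandler):
    protocol_version = "HTTP/1.1"

    def log_message(self, *args):  # default stderr chatter would duplicate logs
        pass

    def do_POST(self):
        server: ProxyServer = self.server  # type: ignore[assignment]
        if self.path != "/donate":
            self._reply(404, DonationResponse(Status.ERR_MALFORMED_ENVELOPE).to_json())
            return
        length = int(self.headers.get("Content-Length", 0))
        body = self.rfile.read(length)
        status_code, reply, outcome, outbound = server.forward_body(body)
        server.record(
            client_address=f"{self.client_address[0]}:{self.client_address[1]}",
            outcome=outcome,
            payload_size=len(body),
            outbound=outbound,
        )
        self._reply(status_code, reply)
        del body  # buffers released with the transaction

    def _reply(self, code: int, body: bytes):
        self.send_response(code)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)


class ProxyServer:
    """In-process HTTP proxy bound to a loopback address.

    Parameters
    ----------
    upstream_url:
        Base URL of the donation database (e.g. ``http://127.0.0.1:8443``).
    storage_root:
        Directory the statelessness audit scans; the proxy never writes here.
    listen:
        ``(host, port)``; port 0 picks a free port.
    """

    def __init__(
        self,
        upstream_url: str,
        storage_root: str | Path,
        listen: tuple[str, int] = ("127.0.0.1", 0),
    ):
        parts = urlsplit(upstream_url)
        self._upstream_host = parts.hostname or "127.0.0.1"
        self._upstream_port = parts.port or 80
        self.storage_root = Path(storage_root)
        self.storage_root.mkdir(parents=True, exist_ok=True)
        self.access_log: list[ProxyLogEntry] = []
        self.forward_log: list[ForwardRecord] = []
        self._lock = threading.Lock()
        self._pending_outbound: str = ""
        self._httpd = ThreadingHTTPServer(listen, _ProxyHandler)
        # handler reaches us through self.server
        self._httpd.forward_body = self.forward_body  # type: ignore[attr-defined]
        self._httpd.record = self.record  # type: ignore[attr-defined]
        self._thread: threading.Thread | None = None

    # -- lifecycle -----------------------------------------------------
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

    # -- core ----------------------------------------------------------
    def forward_body(self, body: bytes) -> tuple[int, bytes, ForwardOutcome, str]:
        """Validate structure, forward verbatim, relay the reply verbatim.

        Returns (http status, reply body, outcome, proxy outbound address).
        Validation is parse-level only; the proxy is oblivious to content.
        """
        try:
            TransferEnvelope.parse(body)
        except MalformedEnvelope:
            return (
                400,
                DonationResponse(Status.ERR_MALFORMED_ENVELOPE).to_json(),
                ForwardOutcome.MALFORMED_REQUEST,
                "",
            )
        conn = http.client.HTTPConnection(
            self._upstream_host, self._upstream_port, timeout=10
        )
        try:
            conn.putrequest("POST", "/donate")
            conn.putheader("Content-Type", "application/json")
            conn.putheader("Content-Length", str(len(body)))
            conn.endheaders()
            conn.send(body)
            outbound = "%s:%d" % conn.sock.getsockname()[:2]
            resp = conn.getresponse()
            reply = resp.read()
            return resp.status, reply, ForwardOutcome.FORWARDED_OK, outbound
        except (OSError, http.client.HTTPException):
            return (
                503,
                DonationResponse(Status.ERR_UPSTREAM_UNAVAILABLE).to_json(),
                ForwardOutcome.UPSTREAM_ERROR,
                "",
            )
        finally:
            conn.close()

    def record(self, client_address: str, outcome: ForwardOutcome, payload_size: int, outbound: str):
        now = _dt.datetime.now(_dt.timezone.utc).isoformat()
        with self._lock:
            self.access_log.append(
                ProxyLogEntry(now, client_address, outcome, payload_size)
            )
            self.forward_log.append(
                ForwardRecord(now, outcome, payload_size, outbound)
            )


def audit_blindness(
    log_entries: Iterable[object], observed_envelopes: Sequence[TransferEnvelope]
) -> bool:
    """True iff no log entry contains any >=16-byte substring of any
    envelope's ciphertext fields (base64 form)."""
    grams: set[str] = set()
    for entry in log_entries:
        text = json.dumps(entry, default=lambda o: o.__dict__)
        for i in range(len(text) - 15):
            grams.add(text[i : i + 16])
    for env in observed_envelopes:
        for ct in (env.c1_b64, env.c2_b64):
            for i in range(len(ct) - 15):
                if ct[i : i + 16] in grams:
                    return False
    return True


def assert_stateless(proxy_storage_root: str | Path) -> bool:
    """True iff the proxy's persistent storage holds no files at all."""
    root = Path(proxy_storage_root)
    if not root.exists():
        return True
    return not any(p.is_file() for p in root.rglob("*"))
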