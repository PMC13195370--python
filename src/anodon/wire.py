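"""Wire protocol shared by client, proxy and server.

A donation is POSTed to ``/donate`` as a JSON object with base64 ciphertext
fields; responses are JSON ``{"status": ...}``.  This module holds only the
neutral encoding layer: it never touches keys or plaintext, so both the
proxy (which must not be able to decrypt) and the server can depend on it.
It deliberately imports nothing from the cryptographic modules at module
level — the proxy's dependency graph must exclude private-key material,
which the test suite asserts statically.
"""

from __future__ import annotations

import base64
import binascii
import json
from dataclasses import dataclass
from enum import Enum

ENVELOPE_VERSION = 1


class Status(str, Enum):
    OK = "OK"
    ERR_MALFORMED_ENVELOPE = "ERR_MALFORMED_ENVELOPE"
    ERR_DECRYPT_KEY = "ERR_DECRYPT_KEY"
    ERR_DECRYPT_DATA = "ERR_DECRYPT_DATA"
    ERR_SCHEMA = "ERR_SCHEMA"
    ERR_UPSTREAM_UNAVAILABLE = "ERR_UPSTREAM_UNAVAILABLE"


@dataclass(frozen=True)
class DonationResponse:
    status: Status

    def to_json(self) -> bytes:
        return json.dumps({"status": self.status.value}).encode()

    @classmethod
    def from_json(cls, body: bytes) -> "DonationResponse":
        return cls(status=Status(json.loads(body.decode())["status"]))


class MalformedEnvelope(ValueError):
    """Request body is not a structurally valid transfer envelope."""


@dataclass(frozen=True)
class TransferEnvelope:
    """JSON transport form of the ciphertext pair: base64 c1/c2 plus version."""

    version: int
    c1_b64: str
    c2_b64: str

    def to_json(self) -> bytes:
        return json.dumps(
            {"version": self.version, "c1_b64": self.c1_b64, "c2_b64": self.c2_b64}
        ).encode()

    @classmethod
    def from_envelope(cls, env) -> "TransferEnvelope":
        return cls(
            version=env.version,
            c1_b64=base64.b64encode(env.c1).decode(),
            c2_b64=base64.b64encode(env.c2).decode(),
        )

    def to_envelope(self):
        from .envelope import EncryptedEnvelope  # lazy: keeps wire a leaf module

        return EncryptedEnvelope(
            c1=base64.b64decode(self.c1_b64, validate=True),
            c2=base64.b64decode(self.c2_b64, validate=True),
            version=self.version,
        )

    @classmethod
    def parse(cls, body: bytes) -> "TransferEnvelope":
        """Structural validation only: JSON shape, base64 decodability and
        ciphertext length arithmetic — no cryptographic inspection."""
        try:
            doc = json.loads(body.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as e:
            raise MalformedEnvelope(f"not a JSON envelope: {e}") from None
        if not isinstance(doc, dict) or set(doc) != {"version", "c1_b64", "c2_b64"}:
            raise MalformedEnvelope("envelope must have exactly version/c1_b64/c2_b64")
        if doc["version"] != ENVELOPE_VERSION:
            raise MalformedEnvelope(f"unsupported version {doc['version']!r}")
        if not isinstance(doc["c1_b64"], str) or not isinstance(doc["c2_b64"], str):
            raise MalformedEnvelope("ciphertext fields must be strings")
        env = cls(version=doc["version"], c1_b64=doc["c1_b64"], c2_b64=doc["c2_b64"])
        try:
            c1 = base64.b64decode(env.c1_b64, validate=True)
            c2 = base64.b64decode(env.c2_b64, validate=True)
        except (binascii.Error, ValueError) as e:
            raise MalformedEnvelope(f"invalid base64: {e}") from None
        if len(c1) < 32 or (len(c1) - 16) % 16:
            raise MalformedEnvelope("c1 must be an IV plus whole ciphertext blocks")
        if not c2:
            raise MalformedEnvelope("c2 must be nonempty")
        return env
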