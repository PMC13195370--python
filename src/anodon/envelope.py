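"""Hybrid encryption envelope for one donation.

Each donation uses a fresh 16-byte symmetric key k_S.  The serialized payload
m is encrypted as c1 = IV || AES-128-CBC(k_S, pad(m)) and the key is
encapsulated as c2 = RSA-OAEP(pk_D, k_S).  The pair (c1, c2) is all that ever
leaves the client; it carries no donor identifier, pseudonym or timestamp.
Only the donation database holds sk_D, so an intermediary that observes or
even stores (c1, c2) learns nothing about the plaintext, and compromise of
one donation's k_S affects no other donation.

CBC provides no authenticity: tampering with c2 surfaces as an OAEP
decapsulation failure, tampering with c1 as a padding or downstream CSV
schema failure.  Transport-layer integrity protection is a deployment
concern outside this package.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass

from .crypto import aes
from .crypto.rsa import (
    OAEPDecryptionError,
    RSAPrivateKey,
    RSAPublicKey,
    generate_private_key,
    oaep_decrypt,
    oaep_encrypt,
    private_key_from_pem,
    private_key_to_pem,
    public_key_from_pem,
    public_key_to_pem,
)
from .wire import ENVELOPE_VERSION

SYMMETRIC_KEY_BYTES = 16  # AES-128


class KeyDecapsulationError(ValueError):
    """c2 failed RSA-OAEP decapsulation (tampered or wrong key)."""


class PayloadDecryptionError(ValueError):
    """c1 failed AES-CBC decryption (bad length or PKCS#7 padding)."""


@dataclass(frozen=True)
class DonationKeyPair:
    """The donation database's RSA keypair; sk_D never leaves the operator."""

    private_key: RSAPrivateKey

    @property
    def public_key(self) -> RSAPublicKey:
        return self.private_key.public_key()


@dataclass(frozen=True)
class EncryptedEnvelope:
    """The ciphertext pair (c1, c2) plus a format version.

    c1 = 16-byte IV followed by the CBC ciphertext (a positive multiple of
    16 bytes); c2 is exactly one RSA modulus in length.
    """

    c1: bytes
    c2: bytes
    version: int = ENVELOPE_VERSION

    def __post_init__(self):
        if len(self.c1) < 32 or (len(self.c1) - 16) % 16:
            raise ValueError("c1 must be IV plus a positive multiple of 16 bytes")


def generate_keypair(modulus_bits: int = 2048, rng: random.Random | None = None) -> DonationKeyPair:
    """Generate the donation database keypair (modulus >= 2048 bits)."""
    return DonationKeyPair(private_key=generate_private_key(modulus_bits, rng))


def encrypt(plaintext: bytes, public_key: RSAPublicKey, rng: random.Random | None = None) -> EncryptedEnvelope:
    """Encrypt one donation under a fresh symmetric key.

    Both k_S and the IV are drawn fresh from ``rng`` (or the OS source); the
    key exists only inside this call — nothing derived from it is cached.
    """
    if rng is not None:
        k_s, iv = rng.randbytes(SYMMETRIC_KEY_BYTES), rng.randbytes(16)
    else:
        k_s, iv = os.urandom(SYMMETRIC_KEY_BYTES), os.urandom(16)
    c1 = iv + aes.cbc_encrypt(k_s, iv, plaintext)
    c2 = oaep_encrypt(public_key, k_s, rng)
    return EncryptedEnvelope(c1=c1, c2=c2)


def decrypt(envelope: EncryptedEnvelope, private_key: RSAPrivateKey) -> bytes:
    """Recover the plaintext: decapsulate k_S from c2, then decrypt c1.

    Raises :class:`KeyDecapsulationError` or :class:`PayloadDecryptionError`
    so the server can reply with the matching stage-specific error code.
    """
    try:
        k_s = oaep_decrypt(private_key, envelope.c2)
    except OAEPDecryptionError as e:
        raise KeyDecapsulationError(str(e)) from None
    if len(k_s) != SYMMETRIC_KEY_BYTES:
        raise KeyDecapsulationError("decapsulated key has wrong length")
    iv, body = envelope.c1[:16], envelope.c1[16:]
    try:
        return aes.cbc_decrypt(k_s, iv, body)
    except aes.PaddingError as e:
        raise PayloadDecryptionError(str(e)) from None
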