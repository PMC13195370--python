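"""RSA key generation and OAEP (SHA-256) key encapsulation, with PEM I/O.

The asymmetric half of the donation envelope: the per-donation symmetric key
is encapsulated under the donation database's RSA public key with OAEP
padding (RFC 8017 RSAES-OAEP, SHA-256 for both the label hash and MGF1).
Any decapsulation failure is reported as a single opaque error, as OAEP
requires.

Keys serialize to the interoperable PEM forms (PKCS#8 for the private key,
SubjectPublicKeyInfo for the public key) via a minimal DER encoder; primality
testing uses deterministic Miller-Rabin bases sufficient for the sizes used
here plus random rounds for larger moduli.
"""

from __future__ import annotations

import base64
import hashlib
import math
import os
import random
from dataclasses import dataclass

_E = 65537
_HASH = hashlib.sha256
_HLEN = 32


class OAEPDecryptionError(ValueError):
    """Ciphertext rejected by RSAES-OAEP decoding (single opaque failure)."""


# ---------------------------------------------------------------- primality

_SMALL_PRIMES = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61, 67]


def _is_probable_prime(n: int, rng: random.Random) -> bool:
    if n < 2:
        return False
    for p in _SMALL_PRIMES:
        if n % p == 0:
            return n == p
    d, s = n - 1, 0
    while d % 2 == 0:
        d //= 2
        s += 1
    # fixed strong bases + 16 random rounds: error probability < 4^-16
    for a in _SMALL_PRIMES + [rng.randrange(2, n - 1) for _ in range(16)]:
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(s - 1):
            x = pow(x, 2, n)
            if x == n - 1:
                break
        else:
            return False
    return True


def _gen_prime(bits: int, rng: random.Random) -> int:
    while True:
        cand = rng.getrandbits(bits)
        cand |= (1 << (bits - 1)) | (1 << (bits - 2)) | 1  # full size, odd
        if cand % _E == 1:
            continue
        if _is_probable_prime(cand, rng):
            return cand


# ---------------------------------------------------------------- key types


@dataclass(frozen=True)
class RSAPublicKey:
    n: int
    e: int

    @property
    def size_bytes(self) -> int:
        return (self.n.bit_length() + 7) // 8


@dataclass(frozen=True, repr=False)
class RSAPrivateKey:
    n: int
    e: int
    d: int
    p: int
    q: int

    def __repr__(self):  # never leak secret material into logs/tracebacks
        return f"RSAPrivateKey(bits={self.n.bit_length()})"

    @property
    def size_bytes(self) -> int:
        return (self.n.bit_length() + 7) // 8

    def public_key(self) -> RSAPublicKey:
        return RSAPublicKey(self.n, self.e)


def generate_private_key(modulus_bits: int, rng: random.Random | None = None) -> RSAPrivateKey:
    """Generate an RSA keypair; ``rng`` may be seeded for reproducible tests."""
    if modulus_bits < 2048:
        raise ValueError("modulus must be at least 2048 bits")
    if rng is None:
        rng = random.SystemRandom()
    while True:
        p = _gen_prime(modulus_bits // 2, rng)
        q = _gen_prime(modulus_bits - modulus_bits // 2, rng)
        if p == q:
            continue
        n = p * q
        if n.bit_length() != modulus_bits:
            continue
        lam = (p - 1) * (q - 1) // math.gcd(p - 1, q - 1)
        if math.gcd(_E, lam) != 1:
            continue
        d = pow(_E, -1, lam)
        return RSAPrivateKey(n=n, e=_E, d=d, p=p, q=q)


# ---------------------------------------------------------------- OAEP


def _mgf1(seed: bytes, length: int) -> bytes:
    out = bytearray()
    for counter in range((length + _HLEN - 1) // _HLEN):
        out += _HASH(seed + counter.to_bytes(4, "big")).digest()
    return bytes(out[:length])


def _xor(a: bytes, b: bytes) -> bytes:
    return bytes(x ^ y for x, y in zip(a, b))


def oaep_encrypt(pub: RSAPublicKey, message: bytes, rng: random.Random | None = None) -> bytes:
    """RSAES-OAEP-ENCRYPT with an empty label; returns a modulus-sized ciphertext."""
    k = pub.size_bytes
    if len(message) > k - 2 * _HLEN - 2:
        raise ValueError("message too long for OAEP with this modulus")
    seed = rng.randbytes(_HLEN) if rng is not None else os.urandom(_HLEN)
    lhash = _HASH(b"").digest()
    ps = b"\x00" * (k - len(message) - 2 * _HLEN - 2)
    db = lhash + ps + b"\x01" + message
    masked_db = _xor(db, _mgf1(seed, k - _HLEN - 1))
    masked_seed = _xor(seed, _mgf1(masked_db, _HLEN))
    em = b"\x00" + masked_seed + masked_db
    c = pow(int.from_bytes(em, "big"), pub.e, pub.n)
    return c.to_bytes(k, "big")


def oaep_decrypt(priv: RSAPrivateKey, ciphertext: bytes) -> bytes:
    """RSAES-OAEP-DECRYPT; raises :class:`OAEPDecryptionError` on any failure."""
    k = priv.size_bytes
    if len(ciphertext) != k or k < 2 * _HLEN + 2:
        raise OAEPDecryptionError("decryption error")
    c = int.from_bytes(ciphertext, "big")
    if c >= priv.n:
        raise OAEPDecryptionError("decryption error")
    em = pow(c, priv.d, priv.n).to_bytes(k, "big")
    y, masked_seed, masked_db = em[0], em[1 : 1 + _HLEN], em[1 + _HLEN :]
    seed = _xor(masked_seed, _mgf1(masked_db, _HLEN))
    db = _xor(masked_db, _mgf1(seed, k - _HLEN - 1))
    lhash, rest = db[:_HLEN], db[_HLEN:]
    sep = rest.find(b"\x01")
    bad = y != 0
    bad |= lhash != _HASH(b"").digest()
    bad |= sep == -1 or any(rest[:sep])
    if bad:
        raise OAEPDecryptionError("decryption error")
    return rest[sep + 1 :]


# ---------------------------------------------------------------- DER / PEM

_OID_RSA = bytes.fromhex("06092a864886f70d010101")  # 1.2.840.113549.1.1.1


def _der_len(n: int) -> bytes:
    if n < 0x80:
        return bytes([n])
    body = n.to_bytes((n.bit_length() + 7) // 8, "big")
    return bytes([0x80 | len(body)]) + body


def _der_int(v: int) -> bytes:
    body = v.to_bytes((v.bit_length() + 8) // 8 or 1, "big")
    return b"\x02" + _der_len(len(body)) + body


def _der_seq(*parts: bytes) -> bytes:
    body = b"".join(parts)
    return b"\x30" + _der_len(len(body)) + body


class _DERReader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def _read_len(self) -> int:
        b = self.data[self.pos]
        self.pos += 1
        if b < 0x80:
            return b
        nbytes = b & 0x7F
        v = int.from_bytes(self.data[self.pos : self.pos + nbytes], "big")
        self.pos += nbytes
        return v

    def expect(self, tag: int) -> bytes:
        if self.pos >= len(self.data) or self.data[self.pos] != tag:
            raise ValueError(f"DER: expected tag 0x{tag:02x}")
        self.pos += 1
        n = self._read_len()
        body = self.data[self.pos : self.pos + n]
        self.pos += n
        return body

    def read_int(self) -> int:
        return int.from_bytes(self.expect(0x02), "big")


def _pem_wrap(label: str, der: bytes) -> str:
    b64 = base64.b64encode(der).decode()
    lines = [b64[i : i + 64] for i in range(0, len(b64), 64)]
    return f"-----BEGIN {label}-----\n" + "\n".join(lines) + f"\n-----END {label}-----\n"


def _pem_unwrap(text: str, label: str) -> bytes:
    begin, end = f"-----BEGIN {label}-----", f"-----END {label}-----"
    if begin not in text or end not in text:
        raise ValueError(f"not a {label} PEM")
    body = text.split(begin, 1)[1].split(end, 1)[0]
    return base64.b64decode("".join(body.split()))


def public_key_to_pem(pub: RSAPublicKey) -> str:
    """SubjectPublicKeyInfo PEM."""
    rsa_pub = _der_seq(_der_int(pub.n), _der_int(pub.e))
    alg = _der_seq(_OID_RSA, b"\x05\x00")
    spki = _der_seq(alg, b"\x03" + _der_len(len(rsa_pub) + 1) + b"\x00" + rsa_pub)
    return _pem_wrap("PUBLIC KEY", spki)


def public_key_from_pem(text: str) -> RSAPublicKey:
    der = _pem_unwrap(text, "PUBLIC KEY")
    outer = _DERReader(_DERReader(der).expect(0x30))
    outer.expect(0x30)  # AlgorithmIdentifier (rsaEncryption assumed)
    bitstr = outer.expect(0x03)
    inner = _DERReader(_DERReader(bitstr[1:]).expect(0x30))
    return RSAPublicKey(n=inner.read_int(), e=inner.read_int())


def private_key_to_pem(priv: RSAPrivateKey) -> str:
    """PKCS#8 PEM wrapping the PKCS#1 RSAPrivateKey structure."""
    p, q, d = priv.p, priv.q, priv.d
    rsa_priv = _der_seq(
        _der_int(0),
        _der_int(priv.n),
        _der_int(priv.e),
        _der_int(d),
        _der_int(p),
        _der_int(q),
        _der_int(d % (p - 1)),
        _der_int(d % (q - 1)),
        _der_int(pow(q, -1, p)),
    )
    alg = _der_seq(_OID_RSA, b"\x05\x00")
    pkcs8 = _der_seq(_der_int(0), alg, b"\x04" + _der_len(len(rsa_priv)) + rsa_priv)
    return _pem_wrap("PRIVATE KEY", pkcs8)


def private_key_from_pem(text: str) -> RSAPrivateKey:
    der = _pem_unwrap(text, "PRIVATE KEY")
    outer = _DERReader(_DERReader(der).expect(0x30))
    outer.read_int()  # version
    outer.expect(0x30)  # AlgorithmIdentifier
    rsa_der = outer.expect(0x04)
    r = _DERReader(_DERReader(rsa_der).expect(0x30))
    r.read_int()  # version
    n, e, d, p, q = (r.read_int() for _ in range(5))
    return RSAPrivateKey(n=n, e=e, d=d, p=p, q=q)
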