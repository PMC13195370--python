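"""AES-128 block cipher with CBC mode and PKCS#7 padding.

Self-contained, table-based implementation of the FIPS-197 cipher for the
128-bit key size, plus CBC chaining and PKCS#7 padding — the symmetric half
of the donation envelope.  The S-box and round tables are derived at import
time from the GF(2^8) field arithmetic rather than transcribed, and the
block core is checked against published FIPS-197 / SP 800-38A test vectors
in the test suite.

CBC with a random IV provides confidentiality only; it is malleable and
carries no authenticity.  Tampering is detected downstream, at the padding
check here and at CSV schema validation — callers must treat a
:class:`PaddingError` as a potential integrity failure, not a bug.
"""

from __future__ import annotations

import struct

BLOCK_SIZE = 16
KEY_SIZE = 16  # AES-128


class PaddingError(ValueError):
    """Ciphertext length or PKCS#7 padding is invalid after decryption."""


def _gmul(a: int, b: int) -> int:
    """Multiply in GF(2^8) with the AES polynomial x^8+x^4+x^3+x+1."""
    r = 0
    while b:
        if b & 1:
            r ^= a
        a <<= 1
        if a & 0x100:
            a ^= 0x11B
        b >>= 1
    return r


def _build_tables():
    # S-box: multiplicative inverse in GF(2^8) followed by the affine map.
    inv = [0] * 256
    for x in range(1, 256):
        for y in range(1, 256):
            if _gmul(x, y) == 1:
                inv[x] = y
                break
    sbox = [0] * 256
    for x in range(256):
        b = inv[x]
        s = b
        for shift in (1, 2, 3, 4):
            s ^= ((b << shift) | (b >> (8 - shift))) & 0xFF
        sbox[x] = s ^ 0x63
    inv_sbox = [0] * 256
    for x, s in enumerate(sbox):
        inv_sbox[s] = x

    def ror8(w: int) -> int:
        return ((w >> 8) | (w << 24)) & 0xFFFFFFFF

    # Te0[x] = [2s, s, s, 3s]; Td0[x] = [0e,09,0d,0b] · invS[x]
    te0 = [0] * 256
    td0 = [0] * 256
    for x in range(256):
        s = sbox[x]
        te0[x] = (_gmul(s, 2) << 24) | (s << 16) | (s << 8) | _gmul(s, 3)
        t = inv_sbox[x]
        td0[x] = (
            (_gmul(t, 0x0E) << 24)
            | (_gmul(t, 0x09) << 16)
            | (_gmul(t, 0x0D) << 8)
            | _gmul(t, 0x0B)
        )
    te1 = [ror8(w) for w in te0]
    te2 = [ror8(w) for w in te1]
    te3 = [ror8(w) for w in te2]
    td1 = [ror8(w) for w in td0]
    td2 = [ror8(w) for w in td1]
    td3 = [ror8(w) for w in td2]
    return sbox, inv_sbox, te0, te1, te2, te3, td0, td1, td2, td3


_SBOX, _INV_SBOX, _TE0, _TE1, _TE2, _TE3, _TD0, _TD1, _TD2, _TD3 = _build_tables()

_RCON = [0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36]


class AES128:
    """The raw 16-byte block transform (ECB core); modes build on this."""

    def __init__(self, key: bytes):
        if len(key) != KEY_SIZE:
            raise ValueError("AES-128 requires a 16-byte key")
        self._ek = self._expand(key)
        self._dk = self._invert_schedule(self._ek)

    @staticmethod
    def _expand(key: bytes) -> list[int]:
        w = list(struct.unpack(">4I", key))
        for i in range(4, 44):
            t = w[i - 1]
            if i % 4 == 0:
                t = ((t << 8) | (t >> 24)) & 0xFFFFFFFF  # RotWord
                t = (
                    (_SBOX[(t >> 24) & 0xFF] << 24)
                    | (_SBOX[(t >> 16) & 0xFF] << 16)
                    | (_SBOX[(t >> 8) & 0xFF] << 8)
                    | _SBOX[t & 0xFF]
                )
                t ^= _RCON[i // 4 - 1] << 24
            w.append(w[i - 4] ^ t)
        return w

    @staticmethod
    def _invert_schedule(ek: list[int]) -> list[int]:
        # Equivalent inverse cipher: reverse round order, InvMixColumns on
        # the inner round keys.  [0e,09,0d,0b]·b == Td0[S[b]] per byte.
        dk = [0] * 44
        for r in range(11):
            dk[4 * r : 4 * r + 4] = ek[40 - 4 * r : 44 - 4 * r]
        for i in range(4, 40):
            w = dk[i]
            dk[i] = (
                _TD0[_SBOX[(w >> 24) & 0xFF]]
                ^ _TD1[_SBOX[(w >> 16) & 0xFF]]
                ^ _TD2[_SBOX[(w >> 8) & 0xFF]]
                ^ _TD3[_SBOX[w & 0xFF]]
            )
        return dk

    def encrypt_block(self, block: bytes) -> bytes:
        ek = self._ek
        s0, s1, s2, s3 = struct.unpack(">4I", block)
        s0 ^= ek[0]
        s1 ^= ek[1]
        s2 ^= ek[2]
        s3 ^= ek[3]
        for r in range(1, 10):
            k = 4 * r
            t0 = (
                _TE0[s0 >> 24] ^ _TE1[(s1 >> 16) & 0xFF]
                ^ _TE2[(s2 >> 8) & 0xFF] ^ _TE3[s3 & 0xFF] ^ ek[k]
            )
            t1 = (
                _TE0[s1 >> 24] ^ _TE1[(s2 >> 16) & 0xFF]
                ^ _TE2[(s3 >> 8) & 0xFF] ^ _TE3[s0 & 0xFF] ^ ek[k + 1]
            )
            t2 = (
                _TE0[s2 >> 24] ^ _TE1[(s3 >> 16) & 0xFF]
                ^ _TE2[(s0 >> 8) & 0xFF] ^ _TE3[s1 & 0xFF] ^ ek[k + 2]
            )
            t3 = (
                _TE0[s3 >> 24] ^ _TE1[(s0 >> 16) & 0xFF]
                ^ _TE2[(s1 >> 8) & 0xFF] ^ _TE3[s2 & 0xFF] ^ ek[k + 3]
            )
            s0, s1, s2, s3 = t0, t1, t2, t3
        out = []
        for a, b, c, d, k in (
            (s0, s1, s2, s3, ek[40]),
            (s1, s2, s3, s0, ek[41]),
            (s2, s3, s0, s1, ek[42]),
            (s3, s0, s1, s2, ek[43]),
        ):
            out.append(
                (
                    (_SBOX[a >> 24] << 24)
                    | (_SBOX[(b >> 16) & 0xFF] << 16)
                    | (_SBOX[(c >> 8) & 0xFF] << 8)
                    | _SBOX[d & 0xFF]
                )
                ^ k
            )
        return struct.pack(">4I", *out)

    def decrypt_block(self, block: bytes) -> bytes:
        dk = self._dk
        s0, s1, s2, s3 = struct.unpack(">4I", block)
        s0 ^= dk[0]
        s1 ^= dk[1]
        s2 ^= dk[2]
        s3 ^= dk[3]
        for r in range(1, 10):
            k = 4 * r
            t0 = (
                _TD0[s0 >> 24] ^ _TD1[(s3 >> 16) & 0xFF]
                ^ _TD2[(s2 >> 8) & 0xFF] ^ _TD3[s1 & 0xFF] ^ dk[k]
            )
            t1 = (
                _TD0[s1 >> 24] ^ _TD1[(s0 >> 16) & 0xFF]
                ^ _TD2[(s3 >> 8) & 0xFF] ^ _TD3[s2 & 0xFF] ^ dk[k + 1]
            )
            t2 = (
                _TD0[s2 >> 24] ^ _TD1[(s1 >> 16) & 0xFF]
                ^ _TD2[(s0 >> 8) & 0xFF] ^ _TD3[s3 & 0xFF] ^ dk[k + 2]
            )
            t3 = (
                _TD0[s3 >> 24] ^ _TD1[(s2 >> 16) & 0xFF]
                ^ _TD2[(s1 >> 8) & 0xFF] ^ _TD3[s0 & 0xFF] ^ dk[k + 3]
            )
            s0, s1, s2, s3 = t0, t1, t2, t3
        out = []
        for a, b, c, d, k in (
            (s0, s3, s2, s1, dk[40]),
            (s1, s0, s3, s2, dk[41]),
            (s2, s1, s0, s3, dk[42]),
            (s3, s2, s1, s0, dk[43]),
        ):
            out.append(
                (
                    (_INV_SBOX[a >> 24] << 24)
                    | (_INV_SBOX[(b >> 16) & 0xFF] << 16)
                    | (_INV_SBOX[(c >> 8) & 0xFF] << 8)
                    | _INV_SBOX[d & 0xFF]
                )
                ^ k
            )
        return struct.pack(">4I", *out)


def pkcs7_pad(data: bytes) -> bytes:
    n = BLOCK_SIZE - len(data) % BLOCK_SIZE
    return data + bytes([n]) * n


def pkcs7_unpad(data: bytes) -> bytes:
    if not data or len(data) % BLOCK_SIZE:
        raise PaddingError("padded data length not a positive multiple of block size")
    n = data[-1]
    if not 1 <= n <= BLOCK_SIZE or data[-n:] != bytes([n]) * n:
        raise PaddingError("invalid PKCS#7 padding")
    return data[:-n]


def cbc_encrypt(key: bytes, iv: bytes, plaintext: bytes) -> bytes:
    """AES-128-CBC encrypt with PKCS#7 padding; returns ciphertext (IV excluded)."""
    if len(iv) != BLOCK_SIZE:
        raise ValueError("IV must be 16 bytes")
    cipher = AES128(key)
    data = pkcs7_pad(plaintext)
    out = bytearray()
    prev = iv
    for i in range(0, len(data), BLOCK_SIZE):
        block = bytes(x ^ y for x, y in zip(data[i : i + BLOCK_SIZE], prev))
        prev = cipher.encrypt_block(block)
        out += prev
    return bytes(out)


def cbc_decrypt(key: bytes, iv: bytes, ciphertext: bytes) -> bytes:
    """AES-128-CBC decrypt and strip PKCS#7 padding; raises PaddingError."""
    if len(iv) != BLOCK_SIZE:
        raise ValueError("IV must be 16 bytes")
    if not ciphertext or len(ciphertext) % BLOCK_SIZE:
        raise PaddingError("ciphertext length not a positive multiple of block size")
    cipher = AES128(key)
    out = bytearray()
    prev = iv
    for i in range(0, len(ciphertext), BLOCK_SIZE):
        block = ciphertext[i : i + BLOCK_SIZE]
        plain = cipher.decrypt_block(block)
        out += bytes(x ^ y for x, y in zip(plain, prev))
        prev = block
    return pkcs7_unpad(bytes(out))
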