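"""DES (FIPS 46-3) in ECB mode with PKCS#7 padding, vectorized over blocks.

Expression-array IDAT payloads are single-DES encrypted, so the package
carries its own implementation of the cipher.  The per-block transform is
expressed as numpy table lookups applied to every 8-byte block of the
ciphertext at once: the initial and final permutations are per-byte 64-bit
lookup tables, and each round's expansion + S-box + P-permutation collapses
into eight 64-entry "SP" tables, the classic optimisation for software DES.
The key schedule is computed per call (keys are 8 bytes; parity bits are
ignored, as the standard prescribes).

DES is used here as a codec, not as security: the cipher and its mode are a
pluggable policy (:class:`DesEcbPkcs7`) so an alternative framing can be
swapped in without touching the XML layer.
"""

from __future__ import annotations

import numpy as np

from .errors import MalformedInputError, ValidationError, WrongKeyError

__all__ = [
    "des_encrypt",
    "des_decrypt",
    "des_ecb_raw",
    "DesEcbPkcs7",
    "DEFAULT_CIPHER",
]

# Standard DES tables (bit positions are 1-indexed from the MSB).
_IP = (
    58, 50, 42, 34, 26, 18, 10, 2, 60, 52, 44, 36, 28, 20, 12, 4,
    62, 54, 46, 38, 30, 22, 14, 6, 64, 56, 48, 40, 32, 24, 16, 8,
    57, 49, 41, 33, 25, 17, 9, 1, 59, 51, 43, 35, 27, 19, 11, 3,
    61, 53, 45, 37, 29, 21, 13, 5, 63, 55, 47, 39, 31, 23, 15, 7,
)
_FP = (
    40, 8, 48, 16, 56, 24, 64, 32, 39, 7, 47, 15, 55, 23, 63, 31,
    38, 6, 46, 14, 54, 22, 62, 30, 37, 5, 45, 13, 53, 21, 61, 29,
    36, 4, 44, 12, 52, 20, 60, 28, 35, 3, 43, 11, 51, 19, 59, 27,
    34, 2, 42, 10, 50, 18, 58, 26, 33, 1, 41, 9, 49, 17, 57, 25,
)
_P = (
    16, 7, 20, 21, 29, 12, 28, 17, 1, 15, 23, 26, 5, 18, 31, 10,
    2, 8, 24, 14, 32, 27, 3, 9, 19, 13, 30, 6, 22, 11, 4, 25,
)
_PC1 = (
    57, 49, 41, 33, 25, 17, 9, 1, 58, 50, 42, 34, 26, 18,
    10, 2, 59, 51, 43, 35, 27, 19, 11, 3, 60, 52, 44, 36,
    63, 55, 47, 39, 31, 23, 15, 7, 62, 54, 46, 38, 30, 22,
    14, 6, 61, 53, 45, 37, 29, 21, 13, 5, 28, 20, 12, 4,
)
_PC2 = (
    14, 17, 11, 24, 1, 5, 3, 28, 15, 6, 21, 10,
    23, 19, 12, 4, 26, 8, 16, 7, 27, 20, 13, 2,
    41, 52, 31, 37, 47, 55, 30, 40, 51, 45, 33, 48,
    44, 49, 39, 56, 34, 53, 46, 42, 50, 36, 29, 32,
)
_SHIFTS = (1, 1, 2, 2, 2, 2, 2, 2, 1, 2, 2, 2, 2, 2, 2, 1)

_SBOX = (
    (14, 4, 13, 1, 2, 15, 11, 8, 3, 10, 6, 12, 5, 9, 0, 7,
     0, 15, 7, 4, 14, 2, 13, 1, 10, 6, 12, 11, 9, 5, 3, 8,
     4, 1, 14, 8, 13, 6, 2, 11, 15, 12, 9, 7, 3, 10, 5, 0,
     15, 12, 8, 2, 4, 9, 1, 7, 5, 11, 3, 14, 10, 0, 6, 13),
    (15, 1, 8, 14, 6, 11, 3, 4, 9, 7, 2, 13, 12, 0, 5, 10,
     3, 13, 4, 7, 15, 2, 8, 14, 12, 0, 1, 10, 6, 9, 11, 5,
     0, 14, 7, 11, 10, 4, 13, 1, 5, 8, 12, 6, 9, 3, 2, 15,
     13, 8, 10, 1, 3, 15, 4, 2, 11, 6, 7, 12, 0, 5, 14, 9),
    (10, 0, 9, 14, 6, 3, 15, 5, 1, 13, 12, 7, 11, 4, 2, 8,
     13, 7, 0, 9, 3, 4, 6, 10, 2, 8, 5, 14, 12, 11, 15, 1,
     13, 6, 4, 9, 8, 15, 3, 0, 11, 1, 2, 12, 5, 10, 14, 7,
     1, 10, 13, 0, 6, 9, 8, 7, 4, 15, 14, 3, 11, 5, 2, 12),
    (7, 13, 14, 3, 0, 6, 9, 10, 1, 2, 8, 5, 11, 12, 4, 15,
     13, 8, 11, 5, 6, 15, 0, 3, 4, 7, 2, 12, 1, 10, 14, 9,
     10, 6, 9, 0, 12, 11, 7, 13, 15, 1, 3, 14, 5, 2, 8, 4,
     3, 15, 0, 6, 10, 1, 13, 8, 9, 4, 5, 11, 12, 7, 2, 14),
    (2, 12, 4, 1, 7, 10, 11, 6, 8, 5, 3, 15, 13, 0, 14, 9,
     14, 11, 2, 12, 4, 7, 13, 1, 5, 0, 15, 10, 3, 9, 8, 6,
     4, 2, 1, 11, 10, 13, 7, 8, 15, 9, 12, 5, 6, 3, 0, 14,
     11, 8, 12, 7, 1, 14, 2, 13, 6, 15, 0, 9, 10, 4, 5, 3),
    (12, 1, 10, 15, 9, 2, 6, 8, 0, 13, 3, 4, 14, 7, 5, 11,
     10, 15, 4, 2, 7, 12, 9, 5, 6, 1, 13, 14, 0, 11, 3, 8,
     9, 14, 15, 5, 2, 8, 12, 3, 7, 0, 4, 10, 1, 13, 11, 6,
     4, 3, 2, 12, 9, 5, 15, 10, 11, 14, 1, 7, 6, 0, 8, 13),
    (4, 11, 2, 14, 15, 0, 8, 13, 3, 12, 9, 7, 5, 10, 6, 1,
     13, 0, 11, 7, 4, 9, 1, 10, 14, 3, 5, 12, 2, 15, 8, 6,
     1, 4, 11, 13, 12, 3, 7, 14, 10, 15, 6, 8, 0, 5, 9, 2,
     6, 11, 13, 8, 1, 4, 10, 7, 9, 5, 0, 15, 14, 2, 3, 12),
    (13, 2, 8, 4, 6, 15, 11, 1, 10, 9, 3, 14, 5, 0, 12, 7,
     1, 15, 13, 8, 10, 3, 7, 4, 12, 5, 6, 11, 0, 14, 9, 2,
     7, 11, 4, 1, 9, 12, 14, 2, 0, 6, 10, 13, 15, 3, 5, 8,
     2, 1, 14, 7, 4, 10, 8, 13, 15, 12, 9, 0, 3, 5, 6, 11),
)


def _byte_luts(perm: tuple[int, ...]) -> list[np.ndarray]:
    """Per-input-byte lookup tables realizing a 64->64 bit permutation."""
    luts = [[0] * 256 for _ in range(8)]
    for out_pos, in_bit in enumerate(perm):
        byte_i, bit_i = divmod(in_bit - 1, 8)
        in_mask = 1 << (7 - bit_i)
        out_mask = 1 << (63 - out_pos)
        tbl = luts[byte_i]
        for v in range(256):
            if v & in_mask:
                tbl[v] |= out_mask
    return [np.array(t, dtype=np.uint64) for t in luts]


def _sp_tables() -> list[np.ndarray]:
    """S-box outputs with the P permutation pre-applied, per 6-bit chunk."""
    tables = []
    for i, sbox in enumerate(_SBOX):
        tbl = [0] * 64
        for v in range(64):
            row = ((v >> 4) & 2) | (v & 1)
            col = (v >> 1) & 0xF
            pre = sbox[16 * row + col] << (32 - 4 * (i + 1))
            out = 0
            for j, pbit in enumerate(_P):
                if pre & (1 << (32 - pbit)):
                    out |= 1 << (31 - j)
            tbl[v] = out
        tables.append(np.array(tbl, dtype=np.uint64))
    return tables


_IP_LUT = _byte_luts(_IP)
_FP_LUT = _byte_luts(_FP)
_SP = _sp_tables()


def _apply64(blocks: np.ndarray, luts: list[np.ndarray]) -> np.ndarray:
    out = np.zeros_like(blocks)
    for i in range(8):
        b = (blocks >> np.uint64(8 * (7 - i))) & np.uint64(0xFF)
        out |= luts[i][b]
    return out


def _subkeys(key: bytes) -> list[tuple[int, ...]]:
    """The 16 round keys, each pre-split into eight 6-bit chunks."""
    if len(key) != 8:
        raise ValidationError(f"DES key must be exactly 8 bytes, got {len(key)}")
    k = int.from_bytes(key, "big")
    cd = 0
    for j, bit in enumerate(_PC1):
        if k & (1 << (64 - bit)):
            cd |= 1 << (55 - j)
    c, d = cd >> 28, cd & 0x0FFFFFFF
    keys = []
    for s in _SHIFTS:
        c = ((c << s) | (c >> (28 - s))) & 0x0FFFFFFF
        d = ((d << s) | (d >> (28 - s))) & 0x0FFFFFFF
        cd2 = (c << 28) | d
        k48 = 0
        for j, bit in enumerate(_PC2):
            if cd2 & (1 << (56 - bit)):
                k48 |= 1 << (47 - j)
        keys.append(tuple((k48 >> (42 - 6 * i)) & 0x3F for i in range(8)))
    return keys


def des_ecb_raw(data: bytes, key: bytes, decrypt: bool = False) -> bytes:
    """Raw ECB transform of whole blocks: no padding added or removed."""
    if len(data) % 8:
        raise MalformedInputError(
            f"DES input length {len(data)} is not a multiple of the 8-byte block size"
        )
    keys = _subkeys(key)
    if decrypt:
        keys = keys[::-1]
    if not data:
        return b""
    x = _apply64(np.frombuffer(data, dtype=">u8").astype(np.uint64), _IP_LUT)
    left = (x >> np.uint64(32)) & np.uint64(0xFFFFFFFF)
    right = x & np.uint64(0xFFFFFFFF)
    one, u31, u33 = np.uint64(1), np.uint64(31), np.uint64(33)
    for ks in keys:
        # 34-bit window: R with bit 32 prepended and bit 1 appended, so every
        # 6-bit expansion group is a plain shift-and-mask.
        y = ((right & one) << u33) | (right << one) | (right >> u31)
        f = np.zeros_like(right)
        for i in range(8):
            idx = ((y >> np.uint64(28 - 4 * i)) & np.uint64(0x3F)) ^ np.uint64(ks[i])
            f |= _SP[i][idx]
        left, right = right, left ^ f
    pre = (right << np.uint64(32)) | left
    return _apply64(pre, _FP_LUT).astype(">u8").tobytes()


def _pkcs7_pad(data: bytes) -> bytes:
    n = 8 - len(data) % 8
    return data + bytes([n]) * n


def _pkcs7_unpad(data: bytes) -> bytes:
    if not data:
        raise WrongKeyError("decrypted payload is empty: wrong key or corrupt file")
    n = data[-1]
    if not 1 <= n <= 8 or data[-n:] != bytes([n]) * n:
        raise WrongKeyError(
            "invalid PKCS#7 padding after decryption: wrong key or corrupt file"
        )
    return data[:-n]


def des_encrypt(plaintext: bytes, key: bytes) -> bytes:
    """PKCS#7-pad then DES-ECB encrypt; output length is a multiple of 8."""
    return des_ecb_raw(_pkcs7_pad(plaintext), key)


def des_decrypt(ciphertext: bytes, key: bytes) -> bytes:
    """DES-ECB decrypt then strip PKCS#7 padding.

    Raises
    ------
    WrongKeyError
        When the padding is invalid after decryption — the usual symptom of
        a wrong key or a corrupted final block.
    """
    return _pkcs7_unpad(des_ecb_raw(ciphertext, key, decrypt=True))


class DesEcbPkcs7:
    """Cipher policy used by the encrypted-XML codec.

    The vendor container's true mode and framing are not public; the codec
    therefore talks to this minimal interface so the choice is swappable.
    """

    name = "des-ecb-pkcs7"

    def encrypt(self, plaintext: bytes, key: bytes) -> bytes:
        return des_encrypt(plaintext, key)

    def decrypt(self, ciphertext: bytes, key: bytes) -> bytes:
        return des_decrypt(ciphertext, key)


DEFAULT_CIPHER = DesEcbPkcs7()
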