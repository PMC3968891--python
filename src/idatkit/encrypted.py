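"""Codec for the encrypted-XML expression IDAT dialect.

An expression IDAT is a DES-encrypted XML document.  After decryption the
per-probe data sit in exactly ten Base64-encoded strings, one per child
element of the root; scan metadata are attributes on the root element.
Nine of the ten vectors have documented meanings (IDs, foreground mean/
SD/median/trimmed mean, background mean/SD, bead counts before and after
outlier exclusion); the tenth is retained uninterpreted under its tag name.

Tag names, element widths and the cipher policy are table-driven rather
than hard-coded in logic so the one unverifiable byte-level choice — the
vendor's exact framing — stays isolated and swappable.
"""

from __future__ import annotations

import base64
import binascii
import os
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .des import DEFAULT_CIPHER
from .errors import (
    CorruptFieldError,
    DialectMismatchError,
    MalformedInputError,
    ValidationError,
    WrongKeyError,
)
from .model import ExpressionIdat

__all__ = [
    "read_encrypted_idat",
    "write_encrypted_idat",
    "decode_base64_vector",
    "encode_base64_vector",
    "set_default_key",
    "get_default_key",
    "FIELD_TAGS",
]

ROOT_TAG = "ExpressionIdat"

#: the nine documented vectors: container tag -> (attribute, element dtype)
FIELD_TAGS: dict[str, tuple[str, str]] = {
    "IllumicodeBinData": ("probe_ids", "<i4"),
    "MeanBinData": ("mean", "<f4"),
    "DevBinData": ("sd", "<f4"),
    "MedianBinData": ("median", "<f4"),
    "TrimmedMeanBinData": ("trimmed_mean", "<f4"),
    "BackgroundBinData": ("bg_mean", "<f4"),
    "BackgroundDevBinData": ("bg_sd", "<f4"),
    "NumBeadsBinData": ("n_beads_raw", "<i4"),
    "NumGoodBeadsBinData": ("n_beads_used", "<i4"),
}
_ATTR_TO_TAG = {attr: (tag, dt) for tag, (attr, dt) in FIELD_TAGS.items()}

#: element width assumed for the uninterpreted tenth vector
EXTRA_FIELD_DTYPE = "<i4"

N_DATA_FIELDS = 10

_DTYPE_ALIASES = {"int32": "<i4", "float32": "<f4"}

_default_key: bytes | None = None


def set_default_key(key: bytes | None) -> None:
    """Configure a process-wide fallback DES key for :func:`read_idat`."""
    global _default_key
    if key is not None and len(key) != 8:
        raise ValidationError(f"DES key must be 8 bytes, got {len(key)}")
    _default_key = key


def get_default_key() -> bytes | None:
    return _default_key


def _resolve_dtype(element_type: str) -> np.dtype:
    dt = _DTYPE_ALIASES.get(str(element_type), str(element_type))
    return np.dtype(dt)


def decode_base64_vector(
    text: str, element_type: str = "int32", field: str | None = None
) -> np.ndarray:
    """Base64-decode ``text`` and reinterpret as little-endian numbers."""
    dt = _resolve_dtype(element_type)
    try:
        raw = base64.b64decode(text, validate=True)
    except (binascii.Error, ValueError) as exc:
        raise CorruptFieldError(f"invalid Base64: {exc}", field=field) from exc
    if len(raw) % dt.itemsize:
        raise CorruptFieldError(
            f"decoded byte count {len(raw)} is not a multiple of element "
            f"width {dt.itemsize}",
            field=field,
        )
    return np.frombuffer(raw, dtype=dt).astype(dt.newbyteorder("="))


def encode_base64_vector(values: np.ndarray, element_type: str = "int32") -> str:
    """Exact inverse of :func:`decode_base64_vector` for same-width input."""
    dt = _resolve_dtype(element_type)
    return base64.b64encode(
        np.ascontiguousarray(values, dtype=dt).tobytes()
    ).decode("ascii")


def read_encrypted_idat(
    path: str | os.PathLike, key: bytes, cipher=None
) -> ExpressionIdat:
    """Decrypt and decode an expression IDAT.

    Raises
    ------
    WrongKeyError
        Padding or XML parse failure after decryption (wrong key, or a
        corrupted ciphertext — the two are indistinguishable).
    DialectMismatchError
        The payload is XML but does not carry exactly ten data fields.
    CorruptFieldError
        One of the Base64 vectors is undecodable.
    """
    cipher = cipher or DEFAULT_CIPHER
    ciphertext = Path(path).read_bytes()
    if len(ciphertext) % 8:
        raise MalformedInputError(
            f"{path}: ciphertext length {len(ciphertext)} is not a multiple of 8"
        )
    plaintext = cipher.decrypt(ciphertext, key)
    try:
        root = ET.fromstring(plaintext)
    except ET.ParseError as exc:
        raise WrongKeyError(
            f"{path}: decrypted payload is not well-formed XML "
            f"(wrong key or corrupt file): {exc}"
        ) from exc

    children = list(root)
    tags = [c.tag for c in children]
    if len(children) != N_DATA_FIELDS:
        raise DialectMismatchError(
            f"{path}: expected exactly {N_DATA_FIELDS} data fields, "
            f"found {len(children)}",
            tags=tags,
        )
    arrays: dict[str, np.ndarray] = {}
    extra: tuple[str, np.ndarray] | None = None
    for child in children:
        text = child.text or ""
        if child.tag in FIELD_TAGS:
            attr, dt = FIELD_TAGS[child.tag]
            arrays[attr] = decode_base64_vector(text, dt, field=child.tag)
        else:
            if extra is not None:
                raise DialectMismatchError(
                    f"{path}: more than one unrecognized data field", tags=tags
                )
            extra = (child.tag, decode_base64_vector(text, EXTRA_FIELD_DTYPE,
                                                     field=child.tag))
    missing = [t for t, (a, _) in FIELD_TAGS.items() if a not in arrays]
    if missing:
        raise DialectMismatchError(
            f"{path}: documented data fields missing: {missing}", tags=tags
        )

    lengths = {len(v) for v in arrays.values()}
    if extra is not None:
        lengths.add(len(extra[1]))
    if len(lengths) > 1:
        raise ValidationError(
            f"{path}: decoded vectors disagree on length: {sorted(lengths)}"
        )
    n = lengths.pop() if lengths else 0
    idat = ExpressionIdat(
        n_probes=n,
        extra_field=extra,
        metadata=dict(root.attrib),
        **arrays,
    )
    idat.validate()
    return idat


def write_encrypted_idat(
    idat: ExpressionIdat, path: str | os.PathLike, key: bytes, cipher=None
) -> int:
    """Serialize, encrypt and write; returns the byte count written.

    Deterministic: equal objects with equal keys give byte-identical files
    (attributes sorted, children in documented-tag order, extra field last).
    """
    cipher = cipher or DEFAULT_CIPHER
    idat.validate()
    root = ET.Element(ROOT_TAG)
    for k in sorted(idat.metadata):
        root.set(k, idat.metadata[k])
    for attr, (tag, dt) in _ATTR_TO_TAG.items():
        ET.SubElement(root, tag).text = encode_base64_vector(
            getattr(idat, attr), dt
        )
    if idat.extra_field is not None:
        name, values = idat.extra_field
        ET.SubElement(root, name).text = encode_base64_vector(
            values, EXTRA_FIELD_DTYPE
        )
    plaintext = ET.tostring(root, encoding="utf-8", xml_declaration=True)
    ciphertext = cipher.encrypt(plaintext, key)
    if ciphertext[:4] == b"IDAT" or ciphertext[:2] == b"\x1f\x8b":
        # astronomically unlikely; would break magic-byte dispatch
        raise ValidationError(
            "ciphertext collides with a binary/gzip magic; choose another key"
        )
    Path(path).write_bytes(ciphertext)
    return len(ciphertext)
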