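"""Byte-exact codec for the binary IDAT dialect (genotyping/methylation).

Container layout: 4-byte ASCII magic ``IDAT``, a 64-bit little-endian
format version (3 for every file seen in the wild), a 32-bit field count,
then that many directory entries of (field code: uint16, absolute byte
offset: uint64).  Field bodies live wherever the directory points; arrays
are little-endian and their length comes from field 1000 (the probe count),
which is therefore always read first.  Strings carry a base-128 varint
length prefix and are Latin-1 (scanner software emits single-byte
encodings; Latin-1 never fails to decode).

Field code assignments are centralized in the tables below so a correction
is a one-line change.  Unknown codes are skipped, logged and preserved as
(code, offset) — chip revisions add fields and a reader must tolerate them.
"""

from __future__ import annotations

import io
import logging
import struct
import warnings
from typing import BinaryIO, Iterable

import numpy as np

from .errors import (
    CorruptFileError,
    NotAnIdatError,
    UnsupportedVersionWarning,
    ValidationError,
)
from .model import BinaryIdat, FieldDirectoryEntry, RunInfoEntry

logger = logging.getLogger(__name__)

MAGIC = b"IDAT"
SUPPORTED_VERSION = 3

# Field code table — the container's de facto vocabulary.
FIELD_N_PROBES = 1000
FIELD_PROBE_IDS = 102
FIELD_SD = 103
FIELD_MEAN = 104
FIELD_N_BEADS = 107
FIELD_MID_BLOCK = 200
FIELD_RUN_INFO = 300
FIELD_RED_GREEN = 400
FIELD_BARCODE = 402
FIELD_CHIP_TYPE = 403
FIELD_POSITION = 404
EXTRA_STRING_CODES = (401, 405, 406, 407, 510)

#: per-probe array fields: attribute name -> (code, numpy little-endian dtype)
ARRAY_FIELDS: dict[str, tuple[int, str]] = {
    "probe_ids": (FIELD_PROBE_IDS, "<i4"),
    "sd": (FIELD_SD, "<u2"),
    "mean": (FIELD_MEAN, "<u2"),
    "n_beads": (FIELD_N_BEADS, "<u1"),
}
_CODE_TO_ARRAY = {code: (name, dt) for name, (code, dt) in ARRAY_FIELDS.items()}
_STRING_CODES = {
    FIELD_BARCODE: "barcode",
    FIELD_CHIP_TYPE: "chip_type",
    FIELD_POSITION: "position",
}

_MAX_VARINT_BYTES = 5


def _read_exact(stream: BinaryIO, n: int, what: str) -> bytes:
    if n < 0:
        raise CorruptFileError(f"negative length for {what}", offset=stream.tell())
    data = stream.read(n)
    if len(data) != n:
        raise CorruptFileError(
            f"truncated {what}: wanted {n} bytes, got {len(data)}",
            offset=stream.tell(),
        )
    return data


def decode_varlen_string(stream: BinaryIO) -> str:
    """Decode one length-prefixed string at the current stream position.

    The prefix is a little-endian base-128 varint: 7 data bits per byte,
    high bit set on every byte except the last.
    """
    length = 0
    shift = 0
    for i in range(_MAX_VARINT_BYTES + 1):
        if i == _MAX_VARINT_BYTES:
            raise CorruptFileError(
                "varint length prefix longer than 5 bytes", offset=stream.tell()
            )
        raw = _read_exact(stream, 1, "string length prefix")
        byte = raw[0]
        length |= (byte & 0x7F) << shift
        shift += 7
        if not byte & 0x80:
            break
    return _read_exact(stream, length, "string body").decode("latin-1")


def encode_varlen_string(s: str) -> bytes:
    """Inverse of :func:`decode_varlen_string`."""
    try:
        body = s.encode("latin-1")
    except UnicodeEncodeError as exc:
        raise ValidationError(
            f"string not representable in Latin-1: {s!r}"
        ) from exc
    n = len(body)
    prefix = bytearray()
    while True:
        b = n & 0x7F
        n >>= 7
        if n:
            prefix.append(b | 0x80)
        else:
            prefix.append(b)
            break
    return bytes(prefix) + body


def _normalize_wanted(wanted_fields: Iterable[int | str] | None) -> set[int] | None:
    if wanted_fields is None:
        return None
    codes: set[int] = set()
    for f in wanted_fields:
        if isinstance(f, str):
            if f not in ARRAY_FIELDS:
                raise ValidationError(
                    f"unknown array field name {f!r}; known: {sorted(ARRAY_FIELDS)}"
                )
            codes.add(ARRAY_FIELDS[f][0])
        else:
            codes.add(int(f))
    return codes


def read_binary_idat(
    stream: BinaryIO, wanted_fields: Iterable[int | str] | None = None
) -> BinaryIdat:
    """Parse a binary IDAT container from a seekable byte stream.

    Parameters
    ----------
    stream
        Open binary stream positioned at byte 0.
    wanted_fields
        Optional projection: array field names (``"mean"``) or field codes.
        Only those per-probe arrays are decoded; metadata fields are always
        parsed.  ``None`` decodes everything.

    Raises
    ------
    NotAnIdatError
        Missing ``IDAT`` magic.
    CorruptFileError
        Truncated container, out-of-range directory offset, or decoded
        content that violates the type invariants.
    """
    wanted = _normalize_wanted(wanted_fields)
    stream.seek(0, io.SEEK_END)
    file_len = stream.tell()
    stream.seek(0)

    magic = stream.read(4)
    if len(magic) < 4:
        raise CorruptFileError("file shorter than the 4-byte magic", offset=0)
    if magic != MAGIC:
        raise NotAnIdatError(f"bad magic {magic!r}, expected {MAGIC!r}")
    (version,) = struct.unpack("<q", _read_exact(stream, 8, "format version"))
    if version != SUPPORTED_VERSION:
        warnings.warn(
            f"IDAT format version {version} (supported: {SUPPORTED_VERSION}); "
            "attempting best-effort parse",
            UnsupportedVersionWarning,
            stacklevel=2,
        )
    (n_fields,) = struct.unpack("<i", _read_exact(stream, 4, "field count"))
    if n_fields < 0:
        raise CorruptFileError(f"negative field count {n_fields}", offset=12)
    directory: list[FieldDirectoryEntry] = []
    seen: set[int] = set()
    for _ in range(n_fields):
        code, offset = struct.unpack(
            "<HQ", _read_exact(stream, 10, "directory entry")
        )
        if code in seen:
            raise CorruptFileError(
                f"duplicate field code {code} in directory", offset=stream.tell() - 10
            )
        seen.add(code)
        # offset == file_len is legal only for zero-length bodies (n_probes=0)
        if offset > file_len:
            raise CorruptFileError(
                f"directory offset {offset} for field {code} beyond EOF ({file_len})",
                offset=stream.tell() - 8,
            )
        directory.append(FieldDirectoryEntry(code=code, offset=offset))
    by_code = {e.code: e.offset for e in directory}

    if FIELD_N_PROBES not in by_code:
        raise CorruptFileError("directory has no probe-count field (code 1000)")
    stream.seek(by_code[FIELD_N_PROBES])
    (n_probes,) = struct.unpack("<i", _read_exact(stream, 4, "probe count"))
    if n_probes < 0:
        raise CorruptFileError(
            f"negative probe count {n_probes}", offset=by_code[FIELD_N_PROBES]
        )

    arrays: dict[str, np.ndarray | None] = {k: None for k in ARRAY_FIELDS}
    strings = {"barcode": "", "chip_type": "", "position": ""}
    extra_strings: dict[int, str] = {}
    unknown_fields: dict[int, int] = {}
    red_green = 0
    mid_block = np.zeros(0, dtype=np.int32)
    run_info: list[RunInfoEntry] = []

    for entry in directory:
        code, offset = entry.code, entry.offset
        if code == FIELD_N_PROBES:
            continue
        if code in _CODE_TO_ARRAY:
            name, dt = _CODE_TO_ARRAY[code]
            if wanted is not None and code not in wanted:
                continue
            stream.seek(offset)
            itemsize = np.dtype(dt).itemsize
            raw = _read_exact(stream, n_probes * itemsize, f"array field {name}")
            arrays[name] = np.frombuffer(raw, dtype=dt).astype(dt.lstrip("<"))
        elif code in _STRING_CODES:
            stream.seek(offset)
            strings[_STRING_CODES[code]] = decode_varlen_string(stream)
        elif code in EXTRA_STRING_CODES:
            stream.seek(offset)
            extra_strings[code] = decode_varlen_string(stream)
        elif code == FIELD_RED_GREEN:
            stream.seek(offset)
            (red_green,) = struct.unpack("<i", _read_exact(stream, 4, "red_green"))
        elif code == FIELD_MID_BLOCK:
            stream.seek(offset)
            (count,) = struct.unpack("<i", _read_exact(stream, 4, "mid-block count"))
            if count < 0:
                raise CorruptFileError(f"negative mid-block count {count}", offset=offset)
            raw = _read_exact(stream, 4 * count, "mid-block array")
            mid_block = np.frombuffer(raw, dtype="<i4").astype(np.int32)
        elif code == FIELD_RUN_INFO:
            stream.seek(offset)
            (count,) = struct.unpack("<i", _read_exact(stream, 4, "run-info count"))
            if count < 0:
                raise CorruptFileError(f"negative run-info count {count}", offset=offset)
            run_info = [
                RunInfoEntry(*(decode_varlen_string(stream) for _ in range(5)))
                for _ in range(count)
            ]
        else:
            logger.warning("skipping unknown IDAT field code %d at offset %d", code, offset)
            unknown_fields[code] = offset

    idat = BinaryIdat(
        n_probes=n_probes,
        probe_ids=arrays["probe_ids"],
        mean=arrays["mean"],
        sd=arrays["sd"],
        n_beads=arrays["n_beads"],
        barcode=strings["barcode"],
        chip_type=strings["chip_type"],
        position=strings["position"],
        red_green=red_green,
        mid_block=mid_block,
        run_info=run_info,
        format_version=int(version),
        extra_strings=extra_strings,
        unknown_fields=unknown_fields,
    )
    try:
        idat.validate(require_all_arrays=False)
    except ValidationError as exc:
        raise CorruptFileError(f"decoded content violates invariants: {exc}") from exc
    return idat


def _field_bodies(idat: BinaryIdat) -> dict[int, bytes]:
    bodies: dict[int, bytes] = {FIELD_N_PROBES: struct.pack("<i", idat.n_probes)}
    for name, (code, dt) in ARRAY_FIELDS.items():
        arr = getattr(idat, name)
        bodies[code] = np.ascontiguousarray(arr, dtype=dt).tobytes()
    bodies[FIELD_MID_BLOCK] = struct.pack("<i", len(idat.mid_block)) + np.ascontiguousarray(
        idat.mid_block, dtype="<i4"
    ).tobytes()
    ri = bytearray(struct.pack("<i", len(idat.run_info)))
    for e in idat.run_info:
        for s in (e.run_time, e.block_type, e.block_pars, e.block_code, e.code_version):
            ri += encode_varlen_string(s)
    bodies[FIELD_RUN_INFO] = bytes(ri)
    bodies[FIELD_RED_GREEN] = struct.pack("<i", idat.red_green)
    bodies[FIELD_BARCODE] = encode_varlen_string(idat.barcode)
    bodies[FIELD_CHIP_TYPE] = encode_varlen_string(idat.chip_type)
    bodies[FIELD_POSITION] = encode_varlen_string(idat.position)
    for code in sorted(idat.extra_strings):
        bodies[int(code)] = encode_varlen_string(idat.extra_strings[code])
    return bodies


def write_binary_idat(idat: BinaryIdat, stream: BinaryIO) -> int:
    """Serialize ``idat``; returns the number of bytes written.

    Fields are laid out contiguously in ascending field-code order so equal
    objects always produce byte-identical files.  Invariants are checked
    before anything is written.
    """
    idat.validate(require_all_arrays=True)
    bodies = _field_bodies(idat)
    codes = sorted(bodies)
    header_len = 4 + 8 + 4 + 10 * len(codes)
    offsets: dict[int, int] = {}
    pos = header_len
    for code in codes:
        offsets[code] = pos
        pos += len(bodies[code])
    stream.write(MAGIC)
    stream.write(struct.pack("<q", idat.format_version))
    stream.write(struct.pack("<i", len(codes)))
    for code in codes:
        stream.write(struct.pack("<HQ", code, offsets[code]))
    for code in codes:
        stream.write(bodies[code])
    return pos
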