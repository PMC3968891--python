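"""Shared domain types, format detection and dialect dispatch.

Two decoded-object types exist because the dialects genuinely differ:
genotyping/methylation binary files carry four per-probe fields in scanner
units, expression files carry ten real-valued summary vectors.  Fields
absent from a dialect are absent from its type, not null-filled.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import MalformedInputError, MissingKeyError, NotAnIdatError, ValidationError

GZIP_MAGIC = b"\x1f\x8b"
_BINARY_MAGIC = b"IDAT"

#: timestamp formats accepted for scan dates (scanner convention first)
SCAN_DATE_FORMATS = ("%m/%d/%Y %I:%M:%S %p", "%Y-%m-%d %H:%M:%S")


class IdatKind(Enum):
    """The three IDAT dialects a file on disk can be."""

    BINARY = "binary"
    GZIPPED_BINARY = "gzipped-binary"
    ENCRYPTED_XML = "encrypted-xml"


@dataclass(frozen=True)
class FieldDirectoryEntry:
    """One (field code, byte offset) pair from a binary container's directory."""

    code: int
    offset: int


@dataclass(frozen=True)
class RunInfoEntry:
    """One record of the scanner's embedded processing log."""

    run_time: str = ""
    block_type: str = ""
    block_pars: str = ""
    block_code: str = ""
    code_version: str = ""


def _arrays_equal(a, b) -> bool:
    if a is None or b is None:
        return a is b
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if a.dtype == b.dtype:
        return a.tobytes() == b.tobytes()  # bit-exact, NaN-safe
    return bool(np.array_equal(a, b))


@dataclass(eq=False)
class BinaryIdat:
    """One channel of a genotyping/methylation array, decoded.

    The four per-probe arrays (``probe_ids``, ``mean``, ``sd``, ``n_beads``)
    are parallel and sorted by bead-type ID.  ``mean``/``sd`` are raw
    scanner units in [0, 65535]; whether ``sd`` is a plain standard
    deviation is not documented by the vendor, so it is stored uninterpreted.
    Arrays may be ``None`` when the reader was asked for a projection.
    """

    n_probes: int
    probe_ids: np.ndarray | None = None
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    n_beads: np.ndarray | None = None
    barcode: str = ""
    chip_type: str = ""
    position: str = ""
    red_green: int = 0
    mid_block: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    run_info: list[RunInfoEntry] = field(default_factory=list)
    format_version: int = 3
    extra_strings: dict[int, str] = field(default_factory=dict)
    unknown_fields: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("probe_ids", "mean", "sd", "n_beads"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v))
        self.mid_block = np.asarray(self.mid_block)

    def validate(self, require_all_arrays: bool = True) -> None:
        arrays = {
            "probe_ids": self.probe_ids,
            "mean": self.mean,
            "sd": self.sd,
            "n_beads": self.n_beads,
        }
        if self.n_probes < 0:
            raise ValidationError(f"negative n_probes {self.n_probes}")
        for name, arr in arrays.items():
            if arr is None:
                if require_all_arrays:
                    raise ValidationError(f"array field {name!r} is missing")
                continue
            if arr.ndim != 1 or len(arr) != self.n_probes:
                raise ValidationError(
                    f"{name} has length {len(arr)}, expected n_probes={self.n_probes}"
                )
        if self.probe_ids is not None and len(self.probe_ids) > 1:
            if not np.all(np.diff(self.probe_ids.astype(np.int64)) > 0):
                raise ValidationError("probe_ids not strictly increasing")
        for name, hi in (("mean", 65535), ("sd", 65535), ("n_beads", 255)):
            arr = arrays[name]
            if arr is not None and len(arr) and (
                arr.min() < 0 or arr.max() > hi
            ):
                raise ValidationError(f"{name} values outside [0, {hi}]")

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryIdat):
            return NotImplemented
        return (
            self.n_probes == other.n_probes
            and all(
                _arrays_equal(getattr(self, n), getattr(other, n))
                for n in ("probe_ids", "mean", "sd", "n_beads", "mid_block")
            )
            and (self.barcode, self.chip_type, self.position) ==
                (other.barcode, other.chip_type, other.position)
            and self.red_green == other.red_green
            and self.run_info == other.run_info
            and self.format_version == other.format_version
            and self.extra_strings == other.extra_strings
        )


@dataclass(eq=False)
class ExpressionIdat:
    """A decoded gene-expression IDAT: ten parallel per-probe vectors.

    Intensities are 32-bit floats; IDs and bead counts 32-bit integers.
    ``n_beads_raw``/``n_beads_used`` count beads before and after outlier
    exclusion.  ``extra_field`` holds the tenth encoded vector under its
    container tag name, uninterpreted.
    """

    n_probes: int
    probe_ids: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    median: np.ndarray
    trimmed_mean: np.ndarray
    bg_mean: np.ndarray
    bg_sd: np.ndarray
    n_beads_raw: np.ndarray
    n_beads_used: np.ndarray
    extra_field: tuple[str, np.ndarray] | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    DATA_FIELDS = (
        "probe_ids", "mean", "sd", "median", "trimmed_mean",
        "bg_mean", "bg_sd", "n_beads_raw", "n_beads_used",
    )

    def validate(self) -> None:
        for name in self.DATA_FIELDS:
            arr = np.asarray(getattr(self, name))
            if arr.ndim != 1 or len(arr) != self.n_probes:
                raise ValidationError(
                    f"{name} has length {len(arr)}, expected n_probes={self.n_probes}"
                )
        if self.extra_field is not None and len(self.extra_field[1]) != self.n_probes:
            raise ValidationError("extra_field length differs from n_probes")
        if np.any(np.asarray(self.n_beads_used) > np.asarray(self.n_beads_raw)):
            raise ValidationError("n_beads_used exceeds n_beads_raw for some probe")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionIdat):
            return NotImplemented
        if self.n_probes != other.n_probes or self.metadata != other.metadata:
            return False
        if not all(
            _arrays_equal(getattr(self, n), getattr(other, n)) for n in self.DATA_FIELDS
        ):
            return False
        if (self.extra_field is None) != (other.extra_field is None):
            return False
        if self.extra_field is not None:
            return self.extra_field[0] == other.extra_field[0] and _arrays_equal(
                self.extra_field[1], other.extra_field[1]
            )
        return True


@dataclass
class ScanMetadata:
    """Scan provenance pulled out of a binary IDAT's run-info log."""

    scan_date: str = ""
    scanner_software: list[tuple[str, str]] = field(default_factory=list)
    barcode: str = ""
    chip_type: str = ""
    position: str = ""

    @property
    def scan_date_parsed(self) -> datetime | None:
        """The scan date under the documented conventions, or ``None``.

        An unparseable date is preserved verbatim in ``scan_date`` and
        simply flagged here — real files mix locales and the grammar is
        not published.
        """
        for fmt in SCAN_DATE_FORMATS:
            try:
                return datetime.strptime(self.scan_date, fmt)
            except ValueError:
                continue
        return None


def detect_format(first_bytes: bytes) -> IdatKind:
    """Classify a file by its leading magic bytes (never by extension).

    ``IDAT`` means plain binary, the RFC 1952 gzip magic means a
    gzip-compressed binary file, and anything else is taken to be the
    encrypted-XML expression dialect, which has no magic of its own.
    """
    if len(first_bytes) < 4:
        raise MalformedInputError(
            f"need at least 4 bytes to detect an IDAT dialect, got {len(first_bytes)}"
        )
    if first_bytes[:4] == _BINARY_MAGIC:
        return IdatKind.BINARY
    if first_bytes[:2] == GZIP_MAGIC:
        return IdatKind.GZIPPED_BINARY
    return IdatKind.ENCRYPTED_XML


def read_idat(
    path: str | os.PathLike,
    decryption_key: bytes | None = None,
    wanted_fields: Iterable[int | str] | None = None,
    cipher=None,
) -> BinaryIdat | ExpressionIdat:
    """Read any IDAT dialect, dispatching on the file's magic bytes.

    Gzip-compressed binary files are transparently decompressed.  For the
    encrypted expression dialect a ``decryption_key`` (8 bytes) is
    required; without one (and with no default configured via
    :func:`idatkit.encrypted.set_default_key`) a :class:`MissingKeyError`
    is raised.
    """
    from . import binary, encrypted

    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(4)
        if len(head) < 4:
            raise MalformedInputError(f"{path}: file shorter than 4 bytes")
        kind = detect_format(head)
        if kind is IdatKind.BINARY:
            fh.seek(0)
            return binary.read_binary_idat(fh, wanted_fields=wanted_fields)

    if kind is IdatKind.GZIPPED_BINARY:
        try:
            with gzip.open(path, "rb") as gz:
                payload = gz.read()
        except (OSError, EOFError) as exc:
            from .errors import CorruptFileError

            raise CorruptFileError(f"{path}: broken gzip container: {exc}") from exc
        if payload[:4] != _BINARY_MAGIC:
            raise NotAnIdatError(
                f"{path}: gzip payload does not start with the IDAT magic"
            )
        return binary.read_binary_idat(io.BytesIO(payload), wanted_fields=wanted_fields)

    key = decryption_key if decryption_key is not None else encrypted.get_default_key()
    if key is None:
        raise MissingKeyError(
            f"{path}: encrypted expression IDAT but no decryption key was "
            "provided or configured"
        )
    return encrypted.read_encrypted_idat(path, key, cipher=cipher)


def extract_scan_metadata(idat: BinaryIdat) -> ScanMetadata:
    """Distill batch-effect-relevant provenance from a binary IDAT.

    The scan date comes from the first run-info entry whose block type
    contains the token ``Scan`` (case-insensitive); software identities are
    the deduplicated (block_code, code_version) pairs over the whole log,
    in first-seen order.  Absent information yields empty fields.
    """
    scan_date = ""
    for entry in idat.run_info:
        if "scan" in entry.block_type.lower():
            scan_date = entry.run_time
            break
    software: list[tuple[str, str]] = []
    for entry in idat.run_info:
        pair = (entry.block_code, entry.code_version)
        if pair not in software:
            software.append(pair)
    return ScanMetadata(
        scan_date=scan_date,
        scanner_software=software,
        barcode=idat.barcode,
        chip_type=idat.chip_type,
        position=idat.position,
    )


def as_table(idat: BinaryIdat | ExpressionIdat) -> pd.DataFrame:
    """One row per probe, one column per available data field.

    Column order is fixed per dialect so text dumps are stable; array
    dtypes are preserved so a full-precision text round trip is exact.
    """
    if isinstance(idat, BinaryIdat):
        cols = {"probe_id": idat.probe_ids, "mean": idat.mean, "sd": idat.sd,
                "n_beads": idat.n_beads}
        cols = {k: v for k, v in cols.items() if v is not None}
        return pd.DataFrame(cols)
    data = {"probe_id": idat.probe_ids}
    for name in ("mean", "sd", "median", "trimmed_mean", "bg_mean", "bg_sd",
                 "n_beads_raw", "n_beads_used"):
        data[name] = getattr(idat, name)
    if idat.extra_field is not None:
        data[idat.extra_field[0]] = idat.extra_field[1]
    return pd.DataFrame(data)
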