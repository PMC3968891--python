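"""Exception taxonomy for IDAT and manifest parsing.

All package errors derive from :class:`IdatError` so callers can catch one
base class; structural problems additionally derive from ``ValueError``.
"""

from __future__ import annotations


class IdatError(Exception):
    """Base class for every error raised by idatkit."""


class MalformedInputError(IdatError, ValueError):
    """Input that cannot be interpreted in the expected dialect."""


class NotAnIdatError(MalformedInputError):
    """The file does not carry the binary IDAT magic."""


class CorruptFileError(MalformedInputError):
    """A structurally broken container; ``offset`` is the first offending byte."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)
        self.offset = offset


class CorruptFieldError(MalformedInputError):
    """A single decoded field is unreadable; ``field`` names it."""

    def __init__(self, message: str, field: str | None = None):
        if field:
            message = f"field {field!r}: {message}"
        super().__init__(message)
        self.field = field


class DialectMismatchError(MalformedInputError):
    """Payload parsed but does not match the expected field inventory."""

    def __init__(self, message: str, tags: list[str] | None = None):
        if tags is not None:
            message = f"{message}; tags found: {tags}"
        super().__init__(message)
        self.tags = tags or []


class MissingKeyError(IdatError):
    """An encrypted file was given with no decryption key configured."""


class WrongKeyError(IdatError):
    """Decryption produced garbage: wrong key or corrupt ciphertext."""


class ValidationError(IdatError, ValueError):
    """An in-memory object violates its type invariants."""


class MalformedManifestError(MalformedInputError):
    """A BGX/BPM-CSV manifest missing required structure."""


class EmptyOverlapError(IdatError):
    """A comparison was requested but no probe IDs are shared."""


class UnsupportedVersionWarning(UserWarning):
    """Container format version differs from the supported one; parse is best-effort."""


class ManifestWarning(UserWarning):
    """Recoverable manifest inconsistency (e.g. declared counts off)."""
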