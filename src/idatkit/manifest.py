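"""BGX / BPM-CSV bead-manifest readers and the intensity annotation join.

A BGX manifest is a gzip-compressed sectioned text file: bracketed section
headers (``[Heading]``, ``[Probes]``, ``[Controls]``), each data section a
tab-separated table with a one-line column header.  Column and section
names vary across chip generations, so they are matched case-insensitively
through an alias table.  Binary BPM manifests are not decoded; the
``read_bpm_csv`` reader accepts the text-export dialect with the same
record model.
"""

from __future__ import annotations

import csv
import gzip
import io
import os
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MalformedManifestError, ManifestWarning, ValidationError
from .model import BinaryIdat

__all__ = ["ManifestRecord", "Manifest", "read_bgx", "write_bgx",
           "read_bpm_csv", "annotate"]

_SEQ_RE = re.compile(r"^[ACGTN]*$", re.IGNORECASE)

#: canonical column -> accepted header spellings (lower-cased, stripped)
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "probe_id": ("probe_id", "address_id", "array_address_id", "id",
                 "illumicodeid", "addressa_id"),
    "probe_sequence": ("probe_sequence", "sequence", "allelea_probeseq"),
    "target_id": ("target_id", "ilmn_gene", "symbol", "target", "name"),
}

_HEADING_PROBES = ("number of probes", "probe count")
_HEADING_CONTROLS = ("number of controls", "control count")


@dataclass(frozen=True)
class ManifestRecord:
    """One bead-type design record."""

    probe_id: int
    probe_sequence: str = ""
    target_id: str = ""
    is_control: bool = False

    def validate(self) -> None:
        if not _SEQ_RE.match(self.probe_sequence):
            raise ValidationError(
                f"probe {self.probe_id}: sequence contains non-IUPAC "
                f"characters: {self.probe_sequence!r}"
            )


@dataclass
class Manifest:
    """Array design: regular probes and control probes, plus heading metadata."""

    heading: dict[str, str] = field(default_factory=dict)
    probes: list[ManifestRecord] = field(default_factory=list)
    controls: list[ManifestRecord] = field(default_factory=list)

    def validate(self) -> None:
        for group, name in ((self.probes, "probes"), (self.controls, "controls")):
            ids = [r.probe_id for r in group]
            if len(ids) != len(set(ids)):
                raise ValidationError(f"duplicate probe_id within {name}")
            for r in group:
                r.validate()
        for key, value in self.heading.items():
            kl = key.strip().lower()
            declared = None
            if kl in _HEADING_PROBES:
                declared, actual, what = int(value), len(self.probes), "probes"
            elif kl in _HEADING_CONTROLS:
                declared, actual, what = int(value), len(self.controls), "controls"
            if declared is not None and declared != actual:
                raise ValidationError(
                    f"heading declares {declared} {what}, found {actual}"
                )

    def frame(self) -> pd.DataFrame:
        """All records as a DataFrame (controls flagged, not segregated)."""
        rows = [(r.probe_id, r.probe_sequence, r.target_id, r.is_control)
                for r in self.probes + self.controls]
        return pd.DataFrame(
            rows, columns=["probe_id", "probe_sequence", "target_id", "is_control"]
        )


def _split_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            current = sections.setdefault(stripped[1:-1].strip().lower(), [])
        elif current is not None:
            current.append(line)
    return sections


def _parse_records(lines: list[str], is_control: bool) -> list[ManifestRecord]:
    rows = [ln for ln in lines if ln.strip()]
    if not rows:
        return []
    header = [h.strip().lower() for h in rows[0].split("\t")]
    colmap: dict[str, int] = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for i, h in enumerate(header):
            if h in aliases:
                colmap[canonical] = i
                break
    if "probe_id" not in colmap:
        raise MalformedManifestError(
            f"no recognizable probe-id column among {header}"
        )
    records = []
    for ln in rows[1:]:
        cells = ln.split("\t")

        def cell(name: str) -> str:
            i = colmap.get(name)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        try:
            pid = int(cell("probe_id"))
        except ValueError as exc:
            raise MalformedManifestError(
                f"non-integer probe id {cell('probe_id')!r}"
            ) from exc
        records.append(
            ManifestRecord(
                probe_id=pid,
                probe_sequence=cell("probe_sequence"),
                target_id=cell("target_id"),
                is_control=is_control,
            )
        )
    return records


def read_bgx(path: str | os.PathLike) -> Manifest:
    """Read a BGX manifest (gzip over sectioned TSV; plain text accepted).

    Declared probe/control counts in ``[Heading]`` are cross-checked; a
    mismatch warns but parsing proceeds.  A missing ``[Probes]`` section is
    a :class:`MalformedManifestError`.
    """
    raw = Path(path).read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    text = raw.decode("latin-1")
    sections = _split_sections(text)
    if "probes" not in sections:
        raise MalformedManifestError(f"{path}: no [Probes] section")
    heading: dict[str, str] = {}
    for ln in sections.get("heading", []):
        if ln.strip():
            key, _, value = ln.partition("\t")
            heading[key.strip()] = value.strip()
    manifest = Manifest(
        heading=heading,
        probes=_parse_records(sections["probes"], is_control=False),
        controls=_parse_records(sections.get("controls", []), is_control=True),
    )
    for keys, group, what in (
        (_HEADING_PROBES, manifest.probes, "probes"),
        (_HEADING_CONTROLS, manifest.controls, "controls"),
    ):
        for key, value in heading.items():
            if key.strip().lower() in keys:
                try:
                    declared = int(value)
                except ValueError:
                    continue
                if declared != len(group):
                    warnings.warn(
                        f"{path}: heading declares {declared} {what}, "
                        f"parsed {len(group)}",
                        ManifestWarning,
                        stacklevel=2,
                    )
    return manifest


def write_bgx(manifest: Manifest, path: str | os.PathLike) -> None:
    """Write a manifest in the BGX dialect (deterministic; fixture writer)."""
    buf = io.StringIO()
    buf.write("[Heading]\n")
    heading = dict(manifest.heading)
    heading.setdefault("Number of Probes", str(len(manifest.probes)))
    heading.setdefault("Number of Controls", str(len(manifest.controls)))
    for key in heading:
        buf.write(f"{key}\t{heading[key]}\n")
    for name, group in (("Probes", manifest.probes), ("Controls", manifest.controls)):
        buf.write(f"[{name}]\n")
        buf.write("Probe_Id\tProbe_Sequence\tTarget_Id\n")
        for r in group:
            buf.write(f"{r.probe_id}\t{r.probe_sequence}\t{r.target_id}\n")
    # mtime=0 so equal manifests give byte-identical files
    with open(path, "wb") as fh:
        with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
            gz.write(buf.getvalue().encode("latin-1"))


def read_bpm_csv(path: str | os.PathLike) -> Manifest:
    """Read the BPM text-export dialect: one CSV with an ``is_control`` column."""
    probes: list[ManifestRecord] = []
    controls: list[ManifestRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise MalformedManifestError(f"{path}: empty BPM-CSV file")
        fields = {h.strip().lower(): h for h in reader.fieldnames}

        def col(canonical: str) -> str | None:
            for alias in COLUMN_ALIASES.get(canonical, (canonical,)):
                if alias in fields:
                    return fields[alias]
            return fields.get(canonical)

        id_col = col("probe_id")
        if id_col is None:
            raise MalformedManifestError(
                f"{path}: no recognizable probe-id column among {reader.fieldnames}"
            )
        seq_col, tgt_col = col("probe_sequence"), col("target_id")
        ctl_col = fields.get("is_control")
        for row in reader:
            is_control = str(row.get(ctl_col, "")).strip().lower() in (
                "1", "true", "yes",
            ) if ctl_col else False
            rec = ManifestRecord(
                probe_id=int(row[id_col]),
                probe_sequence=(row.get(seq_col) or "").strip() if seq_col else "",
                target_id=(row.get(tgt_col) or "").strip() if tgt_col else "",
                is_control=is_control,
            )
            (controls if is_control else probes).append(rec)
    return Manifest(probes=probes, controls=controls)


def annotate(idat: BinaryIdat, manifest: Manifest) -> pd.DataFrame:
    """Left-join a binary IDAT's intensities onto the manifest design.

    Every IDAT probe row is retained; probes absent from the manifest get
    empty annotation and are counted in ``result.attrs["n_unmatched"]``.
    Intensity values and row count are never altered.
    """
    left = pd.DataFrame({"probe_id": np.asarray(idat.probe_ids)})
    for name in ("mean", "sd", "n_beads"):
        arr = getattr(idat, name)
        if arr is not None:
            left[name] = arr
    right = manifest.frame()
    merged = left.merge(right, on="probe_id", how="left", indicator=True)
    n_unmatched = int((merged["_merge"] == "left_only").sum())
    merged = merged.drop(columns=["_merge", "probe_sequence"], errors="ignore")
    merged["target_id"] = merged["target_id"].fillna("")
    merged["is_control"] = merged["is_control"].astype("boolean")
    merged.attrs["n_unmatched"] = n_unmatched
    return merged
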