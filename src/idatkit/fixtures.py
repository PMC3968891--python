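"""Deterministic generators for valid and deliberately broken test files.

Everything the readers consume can be produced here, so the whole stack is
testable with no external data.  Binary intensities follow a log-normal
model (location/scale on the log scale) clipped to the 16-bit scanner
range, with per-probe SD a fixed fraction of the mean — a caricature of
real chips that preserves the properties the codecs care about (range,
sortedness, parallel arrays) without claiming biological realism.
Expression summaries are computed from an explicit per-probe set of
simulated bead intensities, so mean/median/SD/trimmed-mean are internally
consistent rather than independent noise.

Every generator is a pure function of its :class:`FixtureProfile`; the
seed is recorded inside the generated file's metadata so fixtures are
self-describing.
"""

from __future__ import annotations

import gzip
import io
import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .des import DEFAULT_CIPHER
from .encrypted import write_encrypted_idat
from .errors import ValidationError
from .manifest import Manifest, ManifestRecord, write_bgx
from .model import BinaryIdat, ExpressionIdat, RunInfoEntry, as_table
from . import binary

__all__ = [
    "FixtureProfile",
    "FIXTURE_DES_KEY",
    "generate_binary_idat",
    "generate_expression_idat",
    "simulate_beads",
    "write_fixture_files",
    "corrupt_file",
    "CORRUPT_MODES",
]

#: arbitrary documented 8-byte DES key used for all generated expression fixtures
FIXTURE_DES_KEY = b"beadchip"

#: symmetric trim fraction for the expression trimmed-mean summary
TRIM_FRACTION = 0.05

#: beads further than this many (raw) MADs from the probe median are outliers
MAD_CUTOFF = 3.0

_CHIP_TYPES = {
    "genotyping": "HumanOmni2.5-8",
    "methylation": "HumanMethylation450",
    "expression": "HumanHT-12 v4",
}


@dataclass(frozen=True)
class FixtureProfile:
    """Study conditions for one generated file.

    ``mean_log``/``sd_log`` parameterize the log-normal intensity model
    (natural-log scale); ``sd_fraction`` sets per-probe SD relative to the
    mean; ``bead_range`` is the inclusive range of bead counts per type.
    """

    platform: str = "methylation"
    n_probes: int = 100
    seed: int = 0
    mean_log: float = math.log(500.0)
    sd_log: float = 0.8
    sd_fraction: float = 0.1
    bead_range: tuple[int, int] = (5, 30)
    control_fraction: float = 0.05

    def validate(self) -> None:
        if self.platform not in _CHIP_TYPES:
            raise ValidationError(
                f"unknown platform {self.platform!r}; one of {sorted(_CHIP_TYPES)}"
            )
        if self.n_probes < 0:
            raise ValidationError("n_probes must be >= 0")
        if not 0.0 <= self.control_fraction <= 1.0:
            raise ValidationError("control_fraction must be in [0, 1]")
        if self.bead_range[0] < 1 or self.bead_range[1] < self.bead_range[0]:
            raise ValidationError(f"bad bead_range {self.bead_range}")


def _probe_ids(rng: np.random.Generator, n: int) -> np.ndarray:
    # strictly increasing by construction
    steps = rng.integers(1, 50, size=n, dtype=np.int64)
    return (10_000 + np.cumsum(steps)).astype(np.int32)


def _run_info(profile: FixtureProfile) -> list[RunInfoEntry]:
    version = "3.3.57" if profile.platform == "methylation" else "2.3.0.13"
    return [
        RunInfoEntry("1/15/2013 2:03:11 PM", "Decoding", "", "AutoDecoder", "1.1.8"),
        RunInfoEntry("2/7/2013 10:31:04 AM", "Scan",
                     f"sherlock=0|chip={_CHIP_TYPES[profile.platform]}",
                     "iScan", version),
        RunInfoEntry("2/7/2013 10:55:12 AM", "Register", "", "iScan", version),
        RunInfoEntry("2/7/2013 10:58:40 AM", "Extract", "", "iScan", version),
    ]


def _manifest_for(profile: FixtureProfile, ids: np.ndarray,
                  rng: np.random.Generator) -> Manifest:
    n = len(ids)
    n_controls = int(round(profile.control_fraction * n))
    is_control = np.zeros(n, dtype=bool)
    if n_controls:
        is_control[rng.choice(n, size=n_controls, replace=False)] = True
    bases = np.array(list("ACGT"))
    probes, controls = [], []
    for i, pid in enumerate(ids):
        seq = "".join(bases[rng.integers(0, 4, size=50)])
        if is_control[i]:
            controls.append(ManifestRecord(int(pid), seq,
                                           f"CTRL_{i:05d}", True))
        else:
            probes.append(ManifestRecord(int(pid), seq, f"GENE_{i:05d}", False))
    return Manifest(
        heading={
            "Descriptor File Name": f"{_CHIP_TYPES[profile.platform]}.bgx",
            "Number of Probes": str(len(probes)),
            "Number of Controls": str(len(controls)),
        },
        probes=probes,
        controls=controls,
    )


def generate_binary_idat(profile: FixtureProfile) -> tuple[BinaryIdat, Manifest]:
    """A valid binary-dialect object plus a manifest covering its IDs."""
    profile.validate()
    if profile.platform not in ("genotyping", "methylation"):
        raise ValidationError(
            f"binary fixtures need a genotyping/methylation platform, "
            f"got {profile.platform!r}"
        )
    ss = np.random.SeedSequence(profile.seed)
    rng_ids, rng_int, rng_man = (np.random.default_rng(c) for c in ss.spawn(3))
    n = profile.n_probes
    ids = _probe_ids(rng_ids, n)
    means = rng_int.lognormal(profile.mean_log, profile.sd_log, size=n)
    means = np.clip(np.round(means), 0, 65535).astype(np.uint16)
    sd = np.clip(np.round(profile.sd_fraction * means.astype(np.float64)),
                 0, 65535).astype(np.uint16)
    lo, hi = profile.bead_range
    n_beads = rng_int.integers(lo, hi + 1, size=n).astype(np.uint8)
    idat = BinaryIdat(
        n_probes=n,
        probe_ids=ids,
        mean=means,
        sd=sd,
        n_beads=n_beads,
        barcode=f"{5700000000 + profile.seed % 10_000_000:010d}",
        chip_type=_CHIP_TYPES[profile.platform],
        position="R01C01",
        red_green=0,
        mid_block=ids[: min(n, 4)].astype(np.int32),
        run_info=_run_info(profile),
        extra_strings={510: f"fixture-seed:{profile.seed}"},
    )
    idat.validate()
    return idat, _manifest_for(profile, ids, rng_man)


def simulate_beads(profile: FixtureProfile) -> list[np.ndarray]:
    """Per-probe simulated bead intensities (the raw material for summaries).

    Deterministic for a given profile; :func:`generate_expression_idat`
    derives every foreground summary from exactly these values, so tests
    can recompute the statistics independently.
    """
    profile.validate()
    ss = np.random.SeedSequence(profile.seed)
    rng = np.random.default_rng(ss.spawn(4)[1])
    lo, hi = profile.bead_range
    counts = rng.integers(lo, hi + 1, size=profile.n_probes)
    return [
        rng.lognormal(profile.mean_log, profile.sd_log, size=int(c)).astype(
            np.float64
        )
        for c in counts
    ]


def _median_sorted(s: np.ndarray) -> float:
    m = len(s)
    return float((s[(m - 1) // 2] + s[m // 2]) / 2.0)


def _retain_beads(beads: np.ndarray) -> np.ndarray:
    """Drop beads beyond MAD_CUTOFF median-absolute-deviations from the median."""
    med = _median_sorted(np.sort(beads))
    dev = np.abs(beads - med)
    mad = _median_sorted(np.sort(dev))
    if mad == 0:
        return beads
    return beads[dev <= MAD_CUTOFF * mad]


def _trimmed_mean(kept: np.ndarray, frac: float) -> float:
    """Symmetric trimmed mean: drop floor(frac*m) beads from each tail."""
    s = np.sort(kept)
    k = int(len(s) * frac)
    return float(s[k: len(s) - k].mean())


def generate_expression_idat(profile: FixtureProfile) -> ExpressionIdat:
    """A valid expression-dialect object with internally consistent summaries."""
    profile.validate()
    if profile.platform != "expression":
        raise ValidationError(
            f"expression fixtures need platform='expression', got {profile.platform!r}"
        )
    ss = np.random.SeedSequence(profile.seed)
    children = ss.spawn(4)
    rng_ids = np.random.default_rng(children[0])
    rng_bg = np.random.default_rng(children[2])
    rng_extra = np.random.default_rng(children[3])
    n = profile.n_probes
    beads = simulate_beads(profile)

    mean = np.empty(n, dtype=np.float32)
    sd = np.empty(n, dtype=np.float32)
    median = np.empty(n, dtype=np.float32)
    trimmed = np.empty(n, dtype=np.float32)
    raw_counts = np.empty(n, dtype=np.int32)
    used_counts = np.empty(n, dtype=np.int32)
    for i, b in enumerate(beads):
        raw_counts[i] = len(b)
        kept = _retain_beads(b)
        used_counts[i] = len(kept)
        mean[i] = kept.mean()
        sd[i] = kept.std(ddof=1) if len(kept) > 1 else 0.0
        median[i] = _median_sorted(np.sort(kept))
        trimmed[i] = _trimmed_mean(kept, TRIM_FRACTION)

    bg_mean = rng_bg.normal(100.0, 10.0, size=n).astype(np.float32)
    bg_sd = np.abs(rng_bg.normal(8.0, 2.0, size=n)).astype(np.float32)
    idat = ExpressionIdat(
        n_probes=n,
        probe_ids=_probe_ids(rng_ids, n),
        mean=mean,
        sd=sd,
        median=median,
        trimmed_mean=trimmed,
        bg_mean=bg_mean,
        bg_sd=bg_sd,
        n_beads_raw=raw_counts,
        n_beads_used=used_counts,
        extra_field=("CodesBinData",
                     rng_extra.integers(0, 2**16, size=n).astype(np.int32)),
        metadata={
            "Barcode": f"{1600000000 + profile.seed % 10_000_000:010d}",
            "ChipType": _CHIP_TYPES["expression"],
            "Section": "A",
            "ScanDate": "2/7/2013 10:31:04 AM",
            "FixtureSeed": str(profile.seed),
        },
    )
    idat.validate()
    return idat


def write_fixture_files(
    profile: FixtureProfile,
    directory: str | os.PathLike,
    gzipped: bool = False,
    key: bytes = FIXTURE_DES_KEY,
) -> dict[str, Path]:
    """Generate and write the full fixture set for one profile.

    Binary platforms produce an ``.idat`` (optionally gzipped), a ``.bgx``
    manifest and a tab-separated truth table; the expression platform
    produces an encrypted ``.idat`` and its truth table.  Returns a name ->
    path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{profile.platform}_{profile.seed}_{profile.n_probes}"
    paths: dict[str, Path] = {}
    if profile.platform == "expression":
        idat = generate_expression_idat(profile)
        idat_path = directory / f"{stem}.idat"
        write_encrypted_idat(idat, idat_path, key)
        paths["idat"] = idat_path
        table = as_table(idat)
    else:
        idat, manifest = generate_binary_idat(profile)
        buf = io.BytesIO()
        binary.write_binary_idat(idat, buf)
        payload = buf.getvalue()
        idat_path = directory / (f"{stem}.idat.gz" if gzipped else f"{stem}.idat")
        if gzipped:
            idat_path.write_bytes(gzip.compress(payload, mtime=0))
        else:
            idat_path.write_bytes(payload)
        paths["idat"] = idat_path
        bgx_path = directory / f"{stem}.bgx"
        write_bgx(manifest, bgx_path)
        paths["bgx"] = bgx_path
        table = as_table(idat)
    truth_path = directory / f"{stem}.truth.tsv"
    table.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


CORRUPT_MODES = ("truncate", "flip_magic", "bad_offset", "bad_base64", "wrong_pad")


def corrupt_file(
    path: str | os.PathLike,
    mode: str,
    key: bytes = FIXTURE_DES_KEY,
    cipher=None,
) -> Path:
    """Derive a deterministically broken copy of a fixture.

    Modes (and the error class each is designed to trigger):

    - ``truncate``   — cut the file mid-array (corrupt-file error)
    - ``flip_magic`` — invert the first magic byte (not-an-idat from the
      binary reader; dialect dispatch will no longer see a binary file)
    - ``bad_offset`` — point one directory entry beyond EOF (corrupt-file)
    - ``bad_base64`` — inject an illegal character into one encoded vector
      of an expression file (corrupt-field error naming the field)
    - ``wrong_pad``  — flip a bit in the final ciphertext block
      (wrong-key-or-corrupt error)

    The corrupted copy is written next to the input with a ``.corrupt``
    suffix and its path returned.
    """
    cipher = cipher or DEFAULT_CIPHER
    path = Path(path)
    data = bytearray(path.read_bytes())
    if mode == "truncate":
        data = data[: max(len(data) * 3 // 5, 17)]
    elif mode == "flip_magic":
        data[0] ^= 0xFF
    elif mode == "bad_offset":
        if data[:4] != b"IDAT":
            raise ValidationError("bad_offset needs a binary fixture")
        # first directory entry's offset starts at byte 18 (4+8+4+2)
        new_offset = (len(data) + 1000).to_bytes(8, "little")
        data[18:26] = new_offset
    elif mode == "bad_base64":
        plaintext = bytearray(cipher.decrypt(bytes(data), key))
        marker = b"<MeanBinData>"
        i = plaintext.find(marker)
        if i < 0:
            raise ValidationError("bad_base64 needs an expression fixture")
        plaintext[i + len(marker)] = ord("!")
        data = bytearray(cipher.encrypt(bytes(plaintext), key))
    elif mode == "wrong_pad":
        data[-1] ^= 0x01
    else:
        raise ValueError(
            f"unknown corruption mode {mode!r}; one of {CORRUPT_MODES}"
        )
    out = path.with_name(path.name + ".corrupt")
    out.write_bytes(bytes(data))
    return out
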