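# Methods

## Scope and model of the format

An IDAT file stores per-bead-type *summary* intensities (never bead-level
data) for one dye channel of one BeadArray section. `idatkit` models the
format as two genuinely different dialects rather than one superset type:

* `BinaryIdat` — the genotyping/methylation container: four parallel
  per-probe arrays (bead-type ID `int32`, mean `uint16`, SD `uint16`, bead
  count `uint8`), plus run-info log, barcode, chip type, section position,
  a red/green flag and a handful of string fields whose semantics the
  vendor never published (preserved verbatim, uninterpreted).
* `ExpressionIdat` — the expression payload: ten parallel vectors (IDs and
  bead counts `int32`, intensities `float32`), with metadata as string
  key/value pairs.

Fields absent from a dialect are absent from its type; nothing is
null-filled across dialects.

### Binary container layout

The layout is the de facto one established by reverse engineering of
vendor files; nothing official documents it. All integers little-endian:
magic `IDAT`, format version (`int64`, expected 3 — any other value warns
and parses best-effort), field count (`int32`), then a directory of
(code `uint16`, absolute offset `uint64`) entries. Field codes are
centralized in one table in `binary.py` (1000 probe count, 102 IDs,
103 SD, 104 mean, 107 bead counts, 200 mid-block, 300 run-info,
400 red/green, 402–404 barcode/chip/position, 401/405–407/510 uninterpreted
strings) so a correction is a one-line change. Array lengths are not
self-describing, so the probe count is always read first and every array
read is validated against it. Unknown codes are skipped, logged and
preserved as (code, offset) — chip revisions add fields, and a reader that
fails on them would be useless in practice. Strings are Latin-1 with a
base-128 varint length prefix (7 data bits per byte, little-endian groups,
at most 5 prefix bytes). The writer emits fields contiguously in ascending
code order, so equal objects produce byte-identical files.

Reader error taxonomy (the vendor gives none, so it is this package's
own): bad magic → `NotAnIdatError`; truncation, out-of-range directory
offsets, negative counts, or decoded content violating the type
invariants → `CorruptFileError` carrying the first offending byte offset;
unknown version → `UnsupportedVersionWarning`, not an error.

### Encrypted expression dialect

The payload is an XML document encrypted with single DES. The cipher is
implemented in-package (FIPS 46-3): the initial/final permutations are
per-byte 64-bit lookup tables and each round collapses expansion, S-boxes
and the P permutation into eight 64-entry tables, applied with numpy over
all blocks of the file at once (~5 MB/s single-core, ample for chip-scale
files). Correctness is pinned by the classic published single-block test
vector and, in the test suite, by an independent naive bit-level
implementation.

The vendor's exact cipher mode, key derivation and framing are not
public. The codec therefore talks to a one-method-pair *cipher policy*
object; the shipped policy is ECB with PKCS#7 padding, and the key is
always injected (argument, configured default, or CLI flag — the package
ships no vendor key). Wrong key and corrupted ciphertext are reported as
one error class (`WrongKeyError`) because they are cryptographically
indistinguishable: both surface as bad padding or non-well-formed XML.

Ten Base64 data vectors are required, matching the dialect's field
inventory. Nine have documented semantics; the field-name → (attribute,
element-width) mapping is a config table (`FIELD_TAGS`), with IDs and bead
counts `int32` and intensities `float32` little-endian — 32-bit floats
match observed file sizes, and real-valued medians/trimmed means rule out
integer storage. The tenth vector is retained under its tag name,
uninterpreted, rather than guessed at. Float vectors survive write → read
bit-exactly; the codec never re-rounds.

### Dispatch

Detection uses leading magic bytes only (`IDAT` → binary, `1f 8b` →
gzipped binary, anything else → encrypted XML), never the file extension:
files in the wild are uniformly named `.idat` regardless of dialect. The
encrypted dialect has no magic of its own, so it is the fallback class —
a consequence is that a binary file with a damaged magic is
indistinguishable from an encrypted file and is reported as a key problem
by the auto-dispatcher; the binary reader itself reports it as
not-an-IDAT.

## Scan metadata

`extract_scan_metadata` takes the scan date from the first run-info entry
whose block type contains the token "Scan" (case-insensitive) and collects
deduplicated (software, version) pairs in first-seen order. Timestamps are
parsed against the scanner's US-style convention (`2/7/2013 10:31:04 AM`)
with an ISO fallback; an unparseable date is preserved verbatim and
flagged `None` rather than coerced, since real files mix locales and no
grammar is published.

## Manifests

BGX is treated as gzip over sectioned TSV. Section and column names are
matched case-insensitively through an alias table (`Probe_Id`/
`Address_Id`/..., `Sequence`/`Probe_Sequence`/..., `Target_Id`/
`ILMN_Gene`/...) because manifests vary across chip generations. Declared
heading counts are cross-checked: a mismatch warns but parsing proceeds; a
missing `[Probes]` section is fatal. Binary BPM decoding is deliberately
out of scope (no public structure to implement against); the BPM-CSV text
dialect carries the same record model. `annotate` is a left join of IDAT
probe IDs onto manifest records: unmatched probes are kept with empty
annotation and counted, and intensity values and row count are never
altered.

## Synthetic fixtures

The generators exist so the codec stack can be exercised deterministically
at any scale; they emulate the *structure* of real files, not their
biology.

* **Intensity model**: per-probe means log-normal with location
  `log(500)` and scale 0.8 on the natural-log scale — a right-skewed
  distribution spanning roughly two decades, clipped to the 16-bit
  scanner range; SD fixed at 10 % of the mean; bead counts uniform on
  [5, 30]. These defaults are a plausible caricature of BeadArray summary
  data; they make no claim of biological realism, and nothing downstream
  interprets the values.
* **Expression summaries are internally consistent**: each probe gets an
  explicit simulated bead set; outliers are beads more than 3
  median-absolute-deviations from the probe median (any deterministic rule
  would do — this one is simple and documented); mean, sample SD
  (`ddof=1`, 0 for a single bead), median and the symmetrically 5 %-trimmed
  mean (drop `floor(0.05·m)` beads per tail) are all computed from the
  retained beads and stored as `float32`. Tests recompute every statistic
  from the same simulated beads through independent routes (numpy/scipy)
  and require exact agreement.
* **Determinism**: every quantity derives from `numpy.random.SeedSequence`
  children of the profile seed, and the seed is recorded inside the file's
  own metadata, so any fixture is self-describing and exactly
  reproducible. Writers are deterministic down to the byte (gzip mtime
  forced to 0, XML attributes sorted, fields in fixed order).
* **Corruption modes** (`truncate`, `flip_magic`, `bad_offset`,
  `bad_base64`, `wrong_pad`) each target one reader error class for
  error-path testing.

What passing fixture-based tests shows: the codecs invert each other
exactly, reject structural damage cleanly, and preserve numbers bit-for-
bit. What it cannot show: agreement with vendor-encrypted production
expression files, whose framing is unverifiable without a vendor key —
that one choice is isolated behind the cipher-policy interface.

## Comparison against text exports

Vendor text exports round; decoded IDATs do not. Each matched (probe,
column) pair is classified *exact* / *within rounding* / *discordant*;
the three counts partition the comparisons by construction. Numeric
choices: rounding is half-to-even (numpy's rule) at a configurable number
of decimals, default 1, since the vendor documents neither its precision
nor its rounding rule; text values are first cast to the IDAT column's
storage dtype, so a full-precision export of `float32` data is recognized
as bit-exact; for integer columns the comparison runs in `float64`
(exact for this range) so fractional perturbations are never silently
truncated. The perturbation guarantees (±0.04 never discordant at one
decimal, ±0.06 always) hold for truth values on the rounding grid —
integers in the binary dialect — which is how the tests construct their
oracle.

## Problem sizes and performance

Round-trip sweeps run 100 randomized fixtures per dialect with probe
counts drawn from {0, 1, 1000, 50000}, exercising the empty, scalar,
typical and chip-scale regimes; the two extreme sizes appear in every
sweep. Chip-scale parses are also timed in the acceptance script as a
smoke check (no bound asserted — timing is hardware-dependent): a 50 000-
probe binary parse is sub-millisecond and an encrypted expression parse a
few tenths of a second on one core, dominated by DES.

## Known limitations

* Binary BPM manifests are not decoded.
* The vendor's true expression-file framing (cipher mode, key) is not
  replicated — only isolated behind an interface.
* Red/green channel pairing is left to callers; no normalization,
  detection p-values or downstream analysis.
* `sd`/`red_green` and several string fields are stored uninterpreted, as
  their semantics are unpublished.
* Format version ≠ 3 is parsed best-effort only.
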