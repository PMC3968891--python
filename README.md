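# idatkit

Read and write Illumina BeadArray **IDAT** files — without vendor software.

Illumina's scanners emit one IDAT file per dye channel per sample section.
The format is proprietary and undocumented, and historically the only route
from an IDAT to usable numbers was the vendor's GenomeStudio text export,
which also drops information the IDAT actually contains (control-probe and
out-of-band intensities, scan dates, software versions). `idatkit` decodes
all three dialects the platform family uses:

| Array type      | File format   | Per-probe data fields |
|-----------------|---------------|-----------------------|
| SNP genotyping  | binary        | 4                     |
| Methylation     | binary        | 4                     |
| Gene expression | encrypted XML | 10                    |

* **Binary dialect** (genotyping, methylation): a field-directory container
  holding four parallel per-probe arrays — bead-type ID, mean intensity,
  intensity SD, bead count — plus barcode, chip type, section position and
  the scanner's run-info log. Gzip-compressed binary files are read
  transparently.
* **Encrypted-XML dialect** (expression): a single-DES-encrypted XML
  document whose per-probe data are ten Base64-encoded vectors: IDs,
  foreground mean/SD/median/trimmed-mean, local background mean/SD, and
  bead counts before and after outlier exclusion. The DES codec is
  implemented in-package (FIPS 46-3, numpy-vectorized over blocks) and
  verified against the classic published single-block worked example.
* **BGX bead manifests** (gzip-compressed sectioned TSV) link bead-type IDs
  to probe sequences, genomic targets and control status; `annotate()`
  joins them onto decoded intensities. A CSV export dialect covers BPM
  manifests.

File dialects are detected by magic bytes, never by extension. A fixture
module generates deterministic, internally consistent files in every
dialect (including deliberately corrupted ones), so the full stack is
testable with no external data.

## Worked example

Generate a small synthetic methylation-style fixture, then inspect it:

```sh
$ idatkit simulate --platform methylation --n-probes 5 --seed 42 --out-dir .
idat: methylation_42_5.idat
bgx: methylation_42_5.bgx
truth: methylation_42_5.truth.tsv

$ idatkit dump methylation_42_5.idat
probe_id	mean	sd	n_beads
10025	1364	136	5
10070	812	81	17
10099	171	17	7
10144	213	21	26
10155	1465	146	16
```

One row per bead type: `mean` and `sd` are summary intensities in raw
16-bit scanner units, `n_beads` is how many beads of that type were
averaged. Scan provenance (useful for batch-effect detection) comes from
the embedded run-info log:

```sh
$ idatkit meta methylation_42_5.idat
scan_date: 2/7/2013 10:31:04 AM
scanner_software: AutoDecoder 1.1.8; iScan 3.3.57
barcode: 5700000042
chip_type: HumanMethylation450
position: R01C01
```

`idatkit compare` classifies every (probe, column) pair against a text
export as bit-exact, equal-after-rounding, or discordant — the tool for
checking a decoded IDAT against a vendor text export, which rounds:

```sh
$ idatkit compare methylation_42_5.idat methylation_42_5.truth.tsv
{
  "n_rows_compared": 15,
  "n_exact": 15,
  "n_within_rounding": 0,
  "n_discordant": 0,
  ...
}
```

Here all 15 compared values (5 probes × 3 columns) are bit-exact because
the truth table was written at full precision.

The same functionality is available as a library:

```python
import idatkit as ik

idat = ik.read_idat("sample_Grn.idat")            # any dialect, auto-detected
meta = ik.extract_scan_metadata(idat)
manifest = ik.read_bgx("HumanMethylation450.bgx")
table = ik.annotate(idat, manifest)               # pandas DataFrame
```

Expression files need their 8-byte DES key: `ik.read_idat(path,
decryption_key=...)` or `idatkit dump path --key ...` (16 hex digits or 8
ASCII characters). The package ships no vendor key; fixtures use the
documented constant `ik.FIXTURE_DES_KEY`.

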