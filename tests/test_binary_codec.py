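"""Binary-dialect codec: varint strings, round trips, projections, fuzzing."""

import io
import struct
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import idatkit as ik
from idatkit.binary import decode_varlen_string, encode_varlen_string

from .conftest import roundtrip_binary


def _varint_oracle(n: int) -> bytes:
    """Independent base-128 little-endian varint encoder."""
    out = bytearray()
    while True:
        out.append((n & 0x7F) | (0x80 if n > 0x7F else 0))
        n >>= 7
        if not n:
            return bytes(out)


class TestVarlenStrings:
    def test_single_byte_length(self):
        stream = io.BytesIO(bytes([0x05]) + b"R01C1")
        assert decode_varlen_string(stream) == "R01C1"

    def test_two_byte_length_prefix(self):
        s = "x" * 200
        encoded = encode_varlen_string(s)
        assert encoded[:2] == bytes([0xC8, 0x01]) == _varint_oracle(200)
        assert decode_varlen_string(io.BytesIO(encoded)) == s

    @given(st.text(alphabet=st.characters(max_codepoint=255), max_size=300))
    def test_roundtrip_identity(self, s):
        assert decode_varlen_string(io.BytesIO(encode_varlen_string(s))) == s

    def test_prefix_matches_varint_oracle_across_lengths(self):
        for n in (0, 1, 127, 128, 200, 16383, 16384, 100000):
            assert encode_varlen_string("a" * n)[: len(_varint_oracle(n))] == \
                _varint_oracle(n)

    def test_overlong_continuation_chain_rejected(self):
        stream = io.BytesIO(bytes([0x80] * 6))
        with pytest.raises(ik.CorruptFileError):
            decode_varlen_string(stream)

    def test_truncated_body_rejected(self):
        stream = io.BytesIO(bytes([0x0A]) + b"abc")
        with pytest.raises(ik.CorruptFileError):
            decode_varlen_string(stream)

    def test_non_latin1_string_rejected_on_encode(self):
        with pytest.raises(ik.ValidationError):
            encode_varlen_string("中")


class TestRoundTrip:
    def test_fixture_roundtrips_every_field(self, binary_fixture):
        idat, _ = binary_fixture
        back = roundtrip_binary(idat)
        assert back == idat
        for name in ("probe_ids", "mean", "sd", "n_beads"):
            np.testing.assert_array_equal(getattr(back, name), getattr(idat, name))
        assert back.run_info == idat.run_info
        assert back.extra_strings == idat.extra_strings

    def test_known_small_fixture_arrays_exact(self):
        idat = ik.BinaryIdat(
            n_probes=5,
            probe_ids=np.array([10, 20, 30, 40, 50], dtype=np.int32),
            mean=np.array([100, 200, 300, 400, 65535], dtype=np.uint16),
            sd=np.array([1, 2, 3, 4, 5], dtype=np.uint16),
            n_beads=np.array([7, 8, 9, 10, 255], dtype=np.uint8),
            barcode="5700000001",
            chip_type="HumanMethylation450",
            position="R02C01",
        )
        back = roundtrip_binary(idat)
        assert back == idat

    def test_write_is_deterministic(self, binary_fixture):
        idat, _ = binary_fixture
        a, b = io.BytesIO(), io.BytesIO()
        ik.write_binary_idat(idat, a)
        ik.write_binary_idat(idat, b)
        assert a.getvalue() == b.getvalue()

    def test_empty_array_edge_case(self):
        idat = ik.BinaryIdat(
            n_probes=0,
            probe_ids=np.zeros(0, np.int32),
            mean=np.zeros(0, np.uint16),
            sd=np.zeros(0, np.uint16),
            n_beads=np.zeros(0, np.uint8),
        )
        back = roundtrip_binary(idat)
        assert back.n_probes == 0
        assert len(back.probe_ids) == 0
        assert back == idat

    @given(st.integers(0, 200), st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_random_valid_objects_roundtrip(self, n, seed):
        rng = np.random.default_rng(seed)
        ids = np.cumsum(rng.integers(1, 100, n)).astype(np.int32)
        idat = ik.BinaryIdat(
            n_probes=n,
            probe_ids=ids,
            mean=rng.integers(0, 65536, n).astype(np.uint16),
            sd=rng.integers(0, 65536, n).astype(np.uint16),
            n_beads=rng.integers(0, 256, n).astype(np.uint8),
            barcode=str(seed),
            run_info=[ik.RunInfoEntry("t", "Scan", "", "iScan", "1.0")],
        )
        assert roundtrip_binary(idat) == idat

    def test_rereading_same_stream_is_stable(self, binary_fixture):
        idat, _ = binary_fixture
        buf = io.BytesIO()
        ik.write_binary_idat(idat, buf)
        buf.seek(0)
        first = ik.read_binary_idat(buf)
        buf.seek(0)
        second = ik.read_binary_idat(buf)
        assert first == second


class TestProjection:
    def test_wanted_fields_populates_only_those_arrays(self, binary_fixture):
        idat, _ = binary_fixture
        buf = io.BytesIO()
        ik.write_binary_idat(idat, buf)
        buf.seek(0)
        partial = ik.read_binary_idat(buf, wanted_fields={"probe_ids", "mean"})
        np.testing.assert_array_equal(partial.probe_ids, idat.probe_ids)
        np.testing.assert_array_equal(partial.mean, idat.mean)
        assert partial.sd is None and partial.n_beads is None
        # metadata still parsed
        assert partial.barcode == idat.barcode
        assert partial.run_info == idat.run_info

    def test_unknown_wanted_field_name_rejected(self, binary_fixture):
        idat, _ = binary_fixture
        buf = io.BytesIO()
        ik.write_binary_idat(idat, buf)
        buf.seek(0)
        with pytest.raises(ik.ValidationError):
            ik.read_binary_idat(buf, wanted_fields={"intensity"})


class TestWriterValidation:
    def test_length_mismatch_rejected_before_writing(self, binary_fixture):
        idat, _ = binary_fixture
        bad = ik.BinaryIdat(
            n_probes=idat.n_probes,
            probe_ids=idat.probe_ids,
            mean=idat.mean[:-1],
            sd=idat.sd,
            n_beads=idat.n_beads,
        )
        buf = io.BytesIO()
        with pytest.raises(ik.ValidationError):
            ik.write_binary_idat(bad, buf)
        assert buf.getvalue() == b""

    def test_unsorted_ids_rejected(self):
        bad = ik.BinaryIdat(
            n_probes=2,
            probe_ids=np.array([5, 5], dtype=np.int32),
            mean=np.array([1, 2], dtype=np.uint16),
            sd=np.array([0, 0], dtype=np.uint16),
            n_beads=np.array([1, 1], dtype=np.uint8),
        )
        with pytest.raises(ik.ValidationError):
            ik.write_binary_idat(bad, io.BytesIO())


class TestErrorPaths:
    def test_bad_magic(self):
        with pytest.raises(ik.NotAnIdatError):
            ik.read_binary_idat(io.BytesIO(b"XDAT" + b"\x00" * 20))

    def test_truncated_header(self):
        with pytest.raises(ik.CorruptFileError):
            ik.read_binary_idat(io.BytesIO(b"IDAT\x03\x00"))

    def test_offset_beyond_eof(self, binary_fixture):
        idat, _ = binary_fixture
        buf = io.BytesIO()
        ik.write_binary_idat(idat, buf)
        data = bytearray(buf.getvalue())
        data[18:26] = struct.pack("<Q", len(data) + 999)
        with pytest.raises(ik.CorruptFileError) as ei:
            ik.read_binary_idat(io.BytesIO(bytes(data)))
        assert ei.value.offset is not None

    def test_truncated_array_reports_offset_not_short_array(self, binary_fixture):
        idat, _ = binary_fixture
        buf = io.BytesIO()
        ik.write_binary_idat(idat, buf)
        data = buf.getvalue()[: int(len(buf.getvalue()) * 0.6)]
        with pytest.raises(ik.CorruptFileError):
            ik.read_binary_idat(io.BytesIO(data))

    def test_unsupported_version_warns_but_parses(self, binary_fixture):
        idat, _ = binary_fixture
        buf = io.BytesIO()
        ik.write_binary_idat(idat, buf)
        data = bytearray(buf.getvalue())
        data[4] = 7  # format version little-endian int64 at bytes 4..11
        with pytest.warns(ik.UnsupportedVersionWarning):
            back = ik.read_binary_idat(io.BytesIO(bytes(data)))
        assert back.format_version == 7
        np.testing.assert_array_equal(back.mean, idat.mean)

    def test_unknown_field_code_skipped_and_recorded(self, binary_fixture):
        idat, _ = binary_fixture
        buf = io.BytesIO()
        ik.write_binary_idat(idat, buf)
        data = bytearray(buf.getvalue())
        # rewrite the mid_block directory code (200) to an unassigned one
        n_fields = struct.unpack_from("<i", data, 12)[0]
        for i in range(n_fields):
            base = 16 + 10 * i
            code = struct.unpack_from("<H", data, base)[0]
            if code == 200:
                struct.pack_into("<H", data, base, 999)
        back = ik.read_binary_idat(io.BytesIO(bytes(data)))
        assert 999 in back.unknown_fields
        assert len(back.mid_block) == 0

    @given(st.data())
    @settings(max_examples=120)
    def test_single_byte_fuzz_never_crashes(self, binary_fixture, data):
        """Any single-byte mutation parses to a valid object or errors cleanly."""
        idat, _ = binary_fixture
        buf = io.BytesIO()
        ik.write_binary_idat(idat, buf)
        raw = bytearray(buf.getvalue())
        pos = data.draw(st.integers(0, len(raw) - 1))
        val = data.draw(st.integers(0, 255).filter(lambda v: v != raw[pos]))
        raw[pos] = val
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = ik.read_binary_idat(io.BytesIO(bytes(raw)))
        except ik.IdatError:
            return
        result.validate(require_all_arrays=False)
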