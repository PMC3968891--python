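"""The fixture generators: determinism, statistical self-consistency, corruption."""

import numpy as np
import pytest
from scipy import stats

import idatkit as ik
from idatkit.fixtures import MAD_CUTOFF, TRIM_FRACTION, _retain_beads


class TestBinaryGenerator:
    def test_same_seed_gives_identical_objects_and_bytes(self, tmp_path):
        p = ik.FixtureProfile(platform="genotyping", n_probes=30, seed=5)
        a, ma = ik.generate_binary_idat(p)
        b, mb = ik.generate_binary_idat(p)
        assert a == b and ma.probes == mb.probes
        pa = ik.write_fixture_files(p, tmp_path / "a")
        pb = ik.write_fixture_files(p, tmp_path / "b")
        assert pa["idat"].read_bytes() == pb["idat"].read_bytes()
        assert pa["bgx"].read_bytes() == pb["bgx"].read_bytes()

    def test_different_seed_differs(self):
        a, _ = ik.generate_binary_idat(ik.FixtureProfile(n_probes=30, seed=1))
        b, _ = ik.generate_binary_idat(ik.FixtureProfile(n_probes=30, seed=2))
        assert a != b

    def test_zero_probes_is_valid(self, tmp_path):
        p = ik.FixtureProfile(platform="methylation", n_probes=0, seed=0)
        idat, _ = ik.generate_binary_idat(p)
        paths = ik.write_fixture_files(p, tmp_path)
        back = ik.read_idat(paths["idat"])
        assert back.n_probes == 0 and len(back.mean) == 0

    def test_generated_object_satisfies_invariants(self, binary_fixture):
        idat, manifest = binary_fixture
        idat.validate(require_all_arrays=True)
        manifest.validate()
        assert np.all(np.diff(idat.probe_ids) > 0)
        assert idat.mean.dtype == np.uint16 and idat.n_beads.dtype == np.uint8
        # manifest covers all idat ids
        ids = {r.probe_id for r in manifest.probes + manifest.controls}
        assert ids == set(int(i) for i in idat.probe_ids)

    def test_run_info_contains_a_scan_entry(self, binary_fixture):
        idat, _ = binary_fixture
        assert any("scan" in e.block_type.lower() for e in idat.run_info)

    def test_sd_is_fixed_fraction_of_mean(self, binary_profile, binary_fixture):
        idat, _ = binary_fixture
        expected = np.clip(
            np.round(binary_profile.sd_fraction * idat.mean.astype(float)),
            0, 65535,
        ).astype(np.uint16)
        np.testing.assert_array_equal(idat.sd, expected)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ik.ValidationError):
            ik.generate_binary_idat(ik.FixtureProfile(platform="expression"))
        with pytest.raises(ik.ValidationError):
            ik.FixtureProfile(n_probes=-1).validate()
        with pytest.raises(ik.ValidationError):
            ik.FixtureProfile(control_fraction=1.5).validate()


class TestExpressionGenerator:
    def test_summaries_recomputable_from_simulated_beads(self, expression_profile):
        """mean/sd/median/trimmed-mean must be *exactly* the statistics of the
        retained simulated beads (float32-rounded), not independent noise."""
        idat = ik.generate_expression_idat(expression_profile)
        beads = ik.simulate_beads(expression_profile)
        assert len(beads) == idat.n_probes
        for i, b in enumerate(beads):
            kept = _retain_beads(b)
            assert idat.n_beads_raw[i] == len(b)
            assert idat.n_beads_used[i] == len(kept)
            assert idat.mean[i] == np.float32(np.mean(kept))
            assert idat.median[i] == np.float32(np.median(kept))
            expected_sd = np.std(kept, ddof=1) if len(kept) > 1 else 0.0
            assert idat.sd[i] == np.float32(expected_sd)
            # scipy's trimmed mean is an independent route to the same trim rule
            assert idat.trimmed_mean[i] == np.float32(
                stats.trim_mean(kept, TRIM_FRACTION)
            )

    def test_median_bounded_by_bead_extremes(self, expression_profile,
                                             expression_fixture):
        beads = ik.simulate_beads(expression_profile)
        for i, b in enumerate(beads):
            assert b.min() <= expression_fixture.median[i] <= b.max()

    def test_outlier_rule_is_mad_based(self):
        beads = np.array([10.0, 11.0, 9.0, 10.5, 9.5, 100.0])
        kept = _retain_beads(beads)
        med = np.median(beads)
        mad = np.median(np.abs(beads - med))
        assert 100.0 not in kept
        assert np.all(np.abs(kept - med) <= MAD_CUTOFF * mad)

    def test_used_never_exceeds_raw(self, expression_fixture):
        assert np.all(expression_fixture.n_beads_used <=
                      expression_fixture.n_beads_raw)

    def test_background_lower_than_foreground_on_average(self, expression_fixture):
        assert expression_fixture.bg_mean.mean() < expression_fixture.mean.mean()

    def test_deterministic_bytes_on_disk(self, tmp_path, expression_profile):
        pa = ik.write_fixture_files(expression_profile, tmp_path / "a")
        pb = ik.write_fixture_files(expression_profile, tmp_path / "b")
        assert pa["idat"].read_bytes() == pb["idat"].read_bytes()

    def test_seed_recorded_in_metadata(self, expression_fixture, expression_profile):
        assert expression_fixture.metadata["FixtureSeed"] == \
            str(expression_profile.seed)


class TestCorruptFile:
    def test_unknown_mode_is_usage_error(self, fixture_files):
        with pytest.raises(ValueError):
            ik.corrupt_file(fixture_files["idat"], "melt")

    @pytest.mark.parametrize("mode,source,error", [
        ("truncate", "idat", ik.CorruptFileError),
        ("bad_offset", "idat", ik.CorruptFileError),
        ("bad_base64", "expr_idat", ik.CorruptFieldError),
        ("wrong_pad", "expr_idat", ik.WrongKeyError),
    ])
    def test_mode_triggers_designated_error(self, fixture_files, mode, source, error):
        bad = ik.corrupt_file(fixture_files[source], mode)
        with pytest.raises(error):
            ik.read_idat(bad, decryption_key=ik.FIXTURE_DES_KEY)

    def test_flip_magic_is_not_an_idat_for_binary_reader(self, fixture_files):
        bad = ik.corrupt_file(fixture_files["idat"], "flip_magic")
        with open(bad, "rb") as fh:
            with pytest.raises(ik.NotAnIdatError):
                ik.read_binary_idat(fh)

    def test_truncate_reports_an_offset(self, fixture_files):
        bad = ik.corrupt_file(fixture_files["idat"], "truncate")
        with pytest.raises(ik.CorruptFileError):
            ik.read_idat(bad)

    def test_bad_base64_names_the_field(self, fixture_files):
        bad = ik.corrupt_file(fixture_files["expr_idat"], "bad_base64")
        with pytest.raises(ik.CorruptFieldError) as ei:
            ik.read_idat(bad, decryption_key=ik.FIXTURE_DES_KEY)
        assert ei.value.field == "MeanBinData"
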