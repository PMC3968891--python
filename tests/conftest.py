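import io

import pytest
from hypothesis import HealthCheck, settings

import idatkit as ik

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def binary_profile():
    return ik.FixtureProfile(platform="methylation", n_probes=25, seed=11)


@pytest.fixture(scope="session")
def expression_profile():
    return ik.FixtureProfile(platform="expression", n_probes=25, seed=12)


@pytest.fixture(scope="session")
def binary_fixture(binary_profile):
    """(BinaryIdat, Manifest) pair for a small methylation-style chip."""
    return ik.generate_binary_idat(binary_profile)


@pytest.fixture(scope="session")
def expression_fixture(expression_profile):
    return ik.generate_expression_idat(expression_profile)


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory, binary_profile, expression_profile):
    """On-disk fixture set: binary, gzipped binary, encrypted, bgx, truths."""
    d = tmp_path_factory.mktemp("fixtures")
    out = dict(ik.write_fixture_files(binary_profile, d))
    gz = ik.write_fixture_files(binary_profile, d / "gz", gzipped=True)
    out["idat_gz"] = gz["idat"]
    expr = ik.write_fixture_files(expression_profile, d)
    out["expr_idat"] = expr["idat"]
    out["expr_truth"] = expr["truth"]
    return out


def roundtrip_binary(idat: ik.BinaryIdat) -> ik.BinaryIdat:
    buf = io.BytesIO()
    ik.write_binary_idat(idat, buf)
    buf.seek(0)
    return ik.read_binary_idat(buf)
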