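import pytest

from mesplice.fixtures import (
    FixtureSpec,
    default_models,
    generate_fixture,
    write_fixture,
)

SMALL_COUNTS = {
    "donor_dinucleotide_loss": 10,
    "acceptor_dinucleotide_loss": 10,
    "native_weakening": 8,
    "deep_intronic_gain": 8,
    "exonic_gain": 8,
    "neutral": 12,
}


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def small_fixture():
    """A 56-variant synthetic genome shared by read-only tests."""
    spec = FixtureSpec(seed=11, n_genes=6, counts=dict(SMALL_COUNTS))
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def small_fixture_files(small_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_files")
    return write_fixture(small_fixture, out)


@pytest.fixture(scope="session")
def transcripts_by_id(small_fixture):
    return {t.transcript_id: t for t in small_fixture.transcripts}
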