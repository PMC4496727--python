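import pytest

from isoscan.fixtures import (
    FixtureConfig,
    fixture_spec,
    make_genome,
    reduced_multiexon_spec,
    reduced_spec,
)


@pytest.fixture(scope="session")
def spec():
    return fixture_spec()


@pytest.fixture(scope="session")
def toy_spec():
    return reduced_spec(order=0)


@pytest.fixture(scope="session")
def toy_multiexon_spec():
    return reduced_multiexon_spec()


@pytest.fixture(scope="session")
def small_genome(spec):
    """One deterministic 3 kb genome with its truth annotation."""
    genome, transcripts = make_genome(FixtureConfig(seed=11, genome_length=3000), spec)
    return genome, transcripts
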