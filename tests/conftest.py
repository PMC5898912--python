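import pytest
from hypothesis import HealthCheck, settings

import introntrap as it

settings.register_profile(
    "suite", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome_truth():
    return it.make_synthetic_genome()


@pytest.fixture(scope="session")
def genome(genome_truth):
    return genome_truth[0]


@pytest.fixture(scope="session")
def truth(genome_truth):
    return genome_truth[1]


@pytest.fixture(scope="session")
def cassettes():
    return it.make_cassette_standins()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Fixture files written once per session (FASTA, GFF3, truth, GenBank)."""
    d = tmp_path_factory.mktemp("fixtures")
    it.make_synthetic_genome(outdir=str(d))
    it.make_cassette_standins(outdir=str(d))
    return d


@pytest.fixture(scope="session")
def gold_bundle(genome, cassettes):
    """End-to-end design for the canonical Gold fixture gene."""
    return it.run_design(genome, "gGold150", cassettes["pM37-like-p1"])
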