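import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from paravirome.align import ScoringParams
from paravirome.catalog import load_catalog


@pytest.fixture(scope="session")
def protein_params():
    return ScoringParams.protein()


@pytest.fixture(scope="session")
def dna_params():
    return ScoringParams.nucleotide()


@pytest.fixture(scope="session")
def virome():
    """The packaged virome catalog."""
    return load_catalog()
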