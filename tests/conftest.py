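import pytest
from hypothesis import settings

from mitostruct.synthetic import generate_canonical_genome

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_genome():
    """The default canonical synthetic mitogenome and its ground truth."""
    return generate_canonical_genome()


@pytest.fixture(scope="session")
def genome(default_genome):
    return default_genome[0]


@pytest.fixture(scope="session")
def truth(default_genome):
    return default_genome[1]
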