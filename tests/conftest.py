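import pytest
from hypothesis import settings

from ibdcea import canonical_parameters

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Canonical base-case parameter set."""
    return canonical_parameters()
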