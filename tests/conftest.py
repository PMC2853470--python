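import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from fragrank import toy_molecule_set


@pytest.fixture(scope="session")
def toy():
    """Fixture molecules by name."""
    return {m.id: m for m in toy_molecule_set()}
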