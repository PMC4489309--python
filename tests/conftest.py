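import pytest

from ionforest import default_registry, gen_peptides


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def random_peptides(registry):
    """A reusable pool of random modified peptides, varied lengths."""
    return gen_peptides(200, (2, 30), registry, ptm_rate=0.1, seed=42)
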