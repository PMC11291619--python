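import pytest

from sdom.simulate import make_allele_db


@pytest.fixture(scope="session")
def db():
    """Default six-allele reference database (deterministic)."""
    return make_allele_db(seed=1)
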