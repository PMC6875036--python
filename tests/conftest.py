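import pytest

from marinerscan.references import default_references
from marinerscan.simulate import make_master


@pytest.fixture(scope="session")
def master():
    """Default master element: 1225 bp, 29 bp TIRs, 346 aa ORF, DD36E."""
    return make_master(seed=1)


@pytest.fixture(scope="session")
def refs():
    return default_references()
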