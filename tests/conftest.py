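import pytest

from nudtphase import load_catalog, surrogate_reference
from nudtphase.align import PairAligner


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def reference():
    return surrogate_reference()


@pytest.fixture(scope="session")
def aligner(reference, catalog):
    return PairAligner(reference, catalog)
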