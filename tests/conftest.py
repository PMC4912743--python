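import pytest

from prefscan import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def set1(catalog):
    return catalog.by_set(1)
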