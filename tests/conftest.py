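import pytest

import tumorsat as ts


@pytest.fixture(scope="session")
def registry():
    return ts.load_registry()


@pytest.fixture(scope="session")
def by_name(registry):
    return ts.registry_by_name(registry)


@pytest.fixture()
def physiology():
    return ts.default_physiology()
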