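import pytest

from rinsig.synthetic import (agonist_complex, antagonist_complex,
                              build_toy_receptor, pocket_probe_complex)

# session-scoped shared fixtures: treat as read-only; tests that mutate
# must copy (model.copy()) or build their own instance


@pytest.fixture(scope="session")
def toy_receptor():
    return build_toy_receptor()


@pytest.fixture(scope="session")
def agonist():
    return agonist_complex(seed=7)


@pytest.fixture(scope="session")
def antagonist():
    return antagonist_complex(seed=7)


@pytest.fixture(scope="session")
def probe():
    return pocket_probe_complex()
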