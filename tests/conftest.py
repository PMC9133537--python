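import pytest

from speechdev import phonology as ph


@pytest.fixture(scope="session")
def vocab45():
    """27 CV + 18 CCV syllables of the adult-production model language."""
    return ph.vocabulary(ph.EXP2_INVENTORY)


@pytest.fixture(scope="session")
def vocab70():
    """50 CV + 20 CCV syllables of the babbling/imitation language."""
    return ph.vocabulary(ph.EXP1_INVENTORY)


@pytest.fixture(scope="session")
def by_sampa(vocab45):
    return {s.sampa: s for s in vocab45}
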