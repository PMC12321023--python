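import pytest
from hypothesis import settings

from solscat.config import RunConfig
from solscat.pipeline import ProfileCalculator
from solscat.synthetic import make_toy_structure

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy30():
    return make_toy_structure(30, seed=1)


@pytest.fixture(scope="session")
def toy50():
    return make_toy_structure(50, seed=2)


@pytest.fixture(scope="session")
def calc30(toy30):
    """Full pipeline (simple excluded volume, hydrated) on the 30-atom toy."""
    return ProfileCalculator(toy30, RunConfig())
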