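import pytest
from hypothesis import settings

from demcvd import default_bundle

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def uk_bundle():
    return default_bundle("UK")


@pytest.fixture(scope="session")
def china_bundle():
    return default_bundle("China")
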