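import pytest
from hypothesis import settings

from dak2fhir import compile_dictionary, published_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dictionary():
    return published_fixture()


@pytest.fixture(scope="session")
def compiled(fixture_dictionary):
    """The built-in published-inventory fixture compiled once per session."""
    return compile_dictionary(fixture_dictionary)
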