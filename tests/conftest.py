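import pytest

from mrmtrace.library import load_library


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def amp(library):
    return library["AMP"]
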