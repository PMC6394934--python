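import pytest

from pupyscreen.panel import load_panel


@pytest.fixture(scope="session")
def registry():
    return load_panel("bundled")
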