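import pytest


@pytest.fixture
def toy_states():
    """Ten 100 s forward states separated by 10 s gaps."""
    return [(i * 110.0, i * 110.0 + 100.0) for i in range(10)]
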