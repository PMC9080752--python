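import pytest

from ovk.opsin_sequences import bovine_rhodopsin


@pytest.fixture(scope="session")
def bovine() -> str:
    return bovine_rhodopsin()
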