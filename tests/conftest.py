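import pytest

from cbb_ants import baseline_params


@pytest.fixture(scope="session")
def baseline():
    """Baseline parameter set (mu at its reference value 0.03)."""
    return baseline_params()
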