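import numpy as np
import pytest

from shpn_cea import load_fixture


@pytest.fixture(scope="session")
def fixture_config():
    """The packaged base-case parameter set (session-wide, treated read-only)."""
    return load_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220518)
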