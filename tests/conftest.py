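import numpy as np
import pytest

from corticostriatal import behavior_synth, value_model


@pytest.fixture(scope="session")
def qagent_log():
    """A moderately sized Q-agent session shared across read-only tests."""
    return behavior_synth.simulate_session(300, value_model.QParams(), rng=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
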