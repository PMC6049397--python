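import numpy as np
import pytest

#: Fixed study seed used throughout the suite, chosen once up front.
SEED = 0


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
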