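import numpy as np
import pytest

from metaglv import CommunityParams, CorrelationSpec


@pytest.fixture
def params_small():
    """A small community in the partial-coexistence regime (fast to integrate)."""
    return CommunityParams(N=20, c=1.0, mu=0.0, sigma=1.0 / np.sqrt(20))


@pytest.fixture
def independent():
    return CorrelationSpec("independent")
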