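import numpy as np
import pytest

from icxfreq.iccl import build_population


@pytest.fixture(scope="session")
def pop():
    """Default ICcl population: bf 0.5-10 kHz step 0.1, best ITD 0."""
    return build_population()


@pytest.fixture(scope="session")
def itd_grid():
    return np.arange(-250.0, 250.0 + 1e-9, 5.0)
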