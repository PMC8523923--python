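import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from recruitpipe.core import ToneBurstSpec


@pytest.fixture
def anow_spec():
    """Low-frequency tone burst as used for overlapped-waveform recording."""
    return ToneBurstSpec(
        frequency=480.0, duration=33.3, rise_fall=1.0, level=60.0, n_repetitions=92
    )


@pytest.fixture
def cap_spec():
    """Mid-frequency tone burst as used for compound-action-potential runs."""
    return ToneBurstSpec(
        frequency=3000.0, duration=13.9, rise_fall=1.0, level=60.0, n_repetitions=128
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
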