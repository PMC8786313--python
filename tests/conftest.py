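import numpy as np
import pytest

from synapdyn.structure_detection import DetectionParams


@pytest.fixture
def manual_params():
    """Detection params with the half-amplitude threshold used by most
    synthetic scenes (background 10, amplitude 200)."""
    return DetectionParams(threshold_mode="manual", threshold_value=110.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
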