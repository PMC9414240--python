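import numpy as np
import pytest

from olivegrove.radiometric import DEFAULT_CALIBRATION
from olivegrove.synthetic_grove import GroveScenario, generate


@pytest.fixture
def calib():
    """The default camera calibration (typical five-band sensor metadata)."""
    return DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def grove():
    """One rendered synthetic grove reused across classifier tests."""
    return generate(GroveScenario(seed=7), capture_id="grove7")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
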