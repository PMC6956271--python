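import numpy as np
import pytest

# Printed dynamic-dialysis slope magnitudes (h^-1) and the bound
# percentages they imply; the control slope calibrates the membrane
# constant.  Used both as fit targets (noiseless inversion) and as
# generator truth.
CONTROL_SLOPE = 0.44
FORMULATION_SLOPES = {
    "QA-Ch": (0.23, 47.7),
    "QA-Ch-S-pro": (0.28, 36.4),
    "NP QA-Ch": (0.37, 15.9),
    "NP QA-Ch-S-pro": (0.37, 15.9),
    "SB-Ch": (0.29, 34.1),
    "NP SB-Ch": (0.41, 6.8),
}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
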