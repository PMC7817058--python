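import numpy as np
import pytest

from ribocomb import GrowthLaws


@pytest.fixture(scope="session")
def laws() -> GrowthLaws:
    """Standard growth-law constants, drug-free growth 1/h."""
    return GrowthLaws()


@pytest.fixture(scope="session")
def small_grid() -> np.ndarray:
    return np.linspace(0.0, 3.0, 21)
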