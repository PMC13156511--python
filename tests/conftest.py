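import numpy as np
import pytest

from hipfall import FallConfigModel, FractureResponseParams, SurrogateConfig


@pytest.fixture
def ramp_params():
    """Noiseless quadratic-angle ramp oracle used across surrogate tests."""
    return FractureResponseParams(
        v_c0=1.8, angle_curvature=0.6, slope=10.0, protector_shift=0.5, noise_sd=0.0
    )


@pytest.fixture
def fall_model():
    return FallConfigModel()


@pytest.fixture
def surrogate_config():
    return SurrogateConfig(seed=3)


@pytest.fixture
def degree_grid():
    return np.arange(-90.0, 91.0, 1.0)
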