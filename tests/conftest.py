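import numpy as np
import pytest
from hypothesis import settings

from seednmr.signal_model import AcquisitionConfig, KernelComposition, RelaxationParams
from seednmr.synthetic_data import load_preset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def relax() -> RelaxationParams:
    """Line-constant relaxation times: oil 100 ms, bound water 0.75 ms."""
    return RelaxationParams(t2_oil_ms=100.0, t2_water_ms=0.75)


@pytest.fixture
def composition() -> KernelComposition:
    return KernelComposition(oil_amplitude_v=2.0, water_amplitude_v=1.0)


@pytest.fixture
def acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture
def maize_preset():
    return load_preset("maize_zd958")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160725)
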