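import numpy as np
import pytest

from echophantom.core import AcousticSample, PhysicalConstants, TissueReference
from echophantom.simulate import SimulationConfig


@pytest.fixture(scope="session")
def constants() -> PhysicalConstants:
    return PhysicalConstants()


@pytest.fixture(scope="session")
def tissue() -> TissueReference:
    return TissueReference()


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Noise-free, single-repeat acquisition for exact signal-level checks."""
    return SimulationConfig(noise_snr=np.inf, n_repeats=1, rng_seed=7)


@pytest.fixture
def layfomm_sample() -> AcousticSample:
    """A specimen with soft-elastomer-like ground truth (1 cm slab)."""
    return AcousticSample(
        name="layfomm-like",
        thickness=0.010,
        mass=1.082e-2,
        volume=1e-5,
        true_velocity=1468.0,
        true_attenuation_at_f0=6.57,
        true_density=1082.0,
        surface_reflectivity=10.0 ** (-22.5 / 20.0),
    )
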