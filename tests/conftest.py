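import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucleoring import synthetic_data as sd

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Small canvas shared by geometry tests; SIM-like anisotropic sampling.
VOXEL_SIZE = (125.0, 40.0, 40.0)
CANVAS = (32, 192, 192)
CENTER = tuple((d - 1) / 2.0 * v for d, v in zip(CANVAS, VOXEL_SIZE))


def make_planar_ring_stack(diameter=240.0, amplitude=100.0, normal=(1.0, 0.0, 0.0),
                           ellipticity=1.0, blur=None, noise_seed=None):
    """One ring centred in the standard canvas, optionally blurred/noisy."""
    spec = sd.RingSpec(
        center=CENTER,
        diameter=diameter,
        normal=normal,
        ellipticity=ellipticity,
        amplitude=amplitude,
    )
    stack = sd.render_rings([spec], CANVAS, VOXEL_SIZE)
    if blur is not None:
        stack = sd.apply_blur(stack, *blur)
    if noise_seed is not None:
        stack = sd.add_noise(stack, sd.NoiseModel(1.0, 2.0, 5.0, noise_seed))
    return spec, stack


@pytest.fixture
def planar_ring():
    """Noise-free, blur-free planar ring of 240 nm diameter."""
    return make_planar_ring_stack()


@pytest.fixture
def full_mask():
    return np.ones(CANVAS, dtype=bool)
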