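import numpy as np
import pytest

from backres import BackModelParams, generate_back, slice_stack
from backres.surface_io import SliceProfile, SliceStack


def make_profile(z, dx=0.5, x0=0.0, y_center=0.0, missing=None):
    return SliceProfile(y_center=y_center, x0=x0, dx=dx,
                        z=np.asarray(z, dtype=float), missing=missing)


def sinusoid_profile(freq, amplitude=1.0, n=512, dx=0.5, phase=0.0, x0=0.0):
    x = x0 + dx * np.arange(n)
    return make_profile(amplitude * np.sin(2 * np.pi * freq * x + phase),
                        dx=dx, x0=x0)


def stack_from_profiles(profiles, thickness=5.0, spacing=10.0):
    return SliceStack(slices=profiles, slab_thickness=thickness,
                      slab_spacing=spacing, source_id="test")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230914)


@pytest.fixture(scope="session")
def small_back_params():
    """Small symmetric back, coarse sampling, no jitter/noise: fast and exact."""
    return BackModelParams(
        width=320.0,
        height=240.0,
        base_components=[(20.0, 0.003, 0.001, 0.0), (3.0, 0.02, 0.004, 0.9)],
        bump_components=[(60.0, 120.0, 30.0, 40.0, 4.0)],
        f_max=0.05,
        sample_spacing=2.0,
        jitter_fraction=0.0,
        noise_amplitude=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_back_stack(small_back_params):
    cloud = generate_back(small_back_params)
    return slice_stack(cloud, slab_thickness=5.0, slab_spacing=20.0, dx=1.0)
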