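import numpy as np
import pytest

from vatprofiler import PhantomSpec, ProfileSpec, generate_phantom, select_slices
from vatprofiler.phantom import DEFAULT_HU


def small_spec(concentration=0.0, family="beta", volume=150.0, seed=0, noise_sd=10.0, **kw):
    """Compact phantom used throughout the suite: 58 mm body, 150 cm³ VAT."""
    hu = {k: (mu, noise_sd) for k, (mu, _) in DEFAULT_HU.items()}
    params = dict(
        grid_shape=(120, 96, 128),
        voxel_spacing=(3.0, 1.0, 1.0),
        body_radius=58.0,
        sat_thickness=8.0,
        muscle_thickness=6.0,
        vat_total_volume=volume,
        vat_profile=ProfileSpec(family=family, concentration=concentration),
        hu_values=hu,
        seed=seed,
    )
    params.update(kw)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def uniform_phantom():
    """Uniform-profile phantom: volume, ground-truth masks, landmarks."""
    return generate_phantom(small_spec(concentration=0.0, seed=11))


@pytest.fixture(scope="session")
def concentrated_phantom():
    """Caudally concentrated phantom (beta profile, c = 2)."""
    return generate_phantom(small_spec(concentration=2.0, seed=7))


@pytest.fixture(scope="session")
def default_plan(uniform_phantom):
    _, _, landmarks = uniform_phantom
    return select_slices(landmarks, spacing_mm=3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
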