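import numpy as np
import pytest

from petlymph import PhantomLesion, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_sphere_phantom():
    """Noise-free phantom with two well-separated spheres (r=10 and r=8 mm)."""
    spec = PhantomSpec(
        grid_shape=(60, 60, 80),
        voxel_spacing_mm=(2.0, 2.0, 2.0),
        background_suv=0.5,
        lesions=[
            PhantomLesion(center_mm=(60.3, 60.7, 40.1), radii_mm=(10, 10, 10), peak_suv=8.0),
            PhantomLesion(center_mm=(30.2, 30.9, 120.4), radii_mm=(8, 8, 8), peak_suv=6.0),
        ],
        seed=1,
    )
    return generate_phantom(spec)
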