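import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import zoneline as zl

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def geom_iso():
    """Small isotropic 1 mm grid for hand-computed geometry cases."""
    return zl.VolumeGeometry(spacing_mm=(1.0, 1.0, 1.0), shape=(8, 8, 8))


@pytest.fixture
def geom_aniso():
    """Clinically shaped grid: 0.5 mm in-plane, 3 mm slices."""
    return zl.VolumeGeometry(spacing_mm=(0.5, 0.5, 3.0), shape=(8, 32, 32))


@pytest.fixture(scope="session")
def small_params():
    """Compact phantom used throughout: fast but with all six structures."""
    return zl.PhantomParams(
        shape=(16, 64, 64),
        spacing_mm=(0.5, 0.5, 3.0),
        prostate_semiaxes_mm=(12.0, 10.0, 20.0),
        pz_shell_mm=4.0,
        cz_base_mm=7.0,
        afs_cap_mm=3.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return zl.generate_phantom(small_params)


def random_blob_mask(rng: np.random.Generator, shape, n_seeds=3, dilations=2) -> np.ndarray:
    """Random connected-ish blobby mask for oracle spot checks."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    idx = tuple(rng.integers(0, s, size=n_seeds) for s in shape)
    mask[idx] = True
    return ndimage.binary_dilation(mask, iterations=dilations)
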