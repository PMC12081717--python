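import numpy as np
import pytest

from mmkidney import phantoms


@pytest.fixture(scope="session")
def axis():
    return np.linspace(2700.0, 3100.0, 201)


@pytest.fixture(scope="session")
def ref_library(axis):
    return phantoms.make_reference_library(3, axis, seed=7)


@pytest.fixture(scope="session")
def mixture_phantom(ref_library):
    spec = phantoms.PhantomSpec(
        kind="spectral_mixture", shape=(48, 48), noise_sigma=0.0, seed=5
    )
    return phantoms.make_spectral_mixture_phantom(ref_library, spec)


@pytest.fixture(scope="session")
def glom_volume():
    """Full-sphere corpuscle phantom: radius 60 um, 2 um voxels, 60 % tuft."""
    spec = phantoms.PhantomSpec(
        kind="glomerulus_volume",
        shape=(70, 70, 70),
        pixel_size_um=2.0,
        z_spacing_um=2.0,
        noise_sigma=0.02,
        seed=4,
    )
    return phantoms.make_glomerulus_volume_phantom(
        spec, radius_um=60.0, mes_fraction=0.6
    )
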