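import numpy as np
import pytest

from ewaldrec import OpticsModel, make_blob_phantom


@pytest.fixture(scope="session")
def toy_optics():
    """Toy optics used throughout: exaggerated wavelength, mild Cs."""
    return OpticsModel(pixel_size=1.25, wavelength=0.15, cs_mm=0.5, amplitude_contrast=0.07)


@pytest.fixture(scope="session")
def small_phantom():
    """48-box textured phantom, 45 A diameter."""
    return make_blob_phantom(48, 1.25, 45.0, n_blobs=80, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
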