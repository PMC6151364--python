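import numpy as np
import pytest

from lvseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless():
    """Noiseless default phantom: (spec, volume, mask, analytic mesh)."""
    spec = PhantomSpec(speckle_scale=0.0, smoothing_sigma=0.0)
    vol, mask, mesh = generate_phantom(spec)
    return spec, vol, mask, mesh


@pytest.fixture(scope="session")
def speckled():
    """Default (speckled, smoothed) phantom."""
    spec = PhantomSpec()
    vol, mask, mesh = generate_phantom(spec)
    return spec, vol, mask, mesh


@pytest.fixture(scope="session")
def atrium_phantom():
    """Atrium-enabled phantom reproducing the LV/LA leak hazard."""
    spec = PhantomSpec(atrium_enabled=True)
    vol, mask, mesh = generate_phantom(spec)
    return spec, vol, mask, mesh


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
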