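import numpy as np
import pytest

from fibralign import FiberFieldSpec, GrayImage, generate_phantom
from fibralign.directionality import SpectrumDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_spectrum(rng):
    """A random 15x15 non-negative modulus matrix posing as a spectrum."""
    mod = rng.uniform(0.0, 5.0, size=(15, 15))
    return SpectrumDistribution(modulus=mod)


def small_phantom(model="wrapped_normal", mu0=0.0, sigma0=10.0, seed=0,
                  image_px=275, n_fibers=100, **kw):
    """A fast, small fibre phantom for pipeline-level tests."""
    kw.setdefault("length_px", (130.0, 25.0))
    spec = FiberFieldSpec(image_px=image_px, n_fibers=n_fibers,
                          orientation_model=model, mu0_deg=mu0,
                          sigma0_deg=sigma0, seed=seed, **kw)
    img, truth = generate_phantom(spec)
    return img, truth, spec


@pytest.fixture
def aligned_phantom():
    return small_phantom(mu0=30.0, sigma0=8.0, seed=3)


@pytest.fixture
def isotropic_phantom():
    return small_phantom(model="uniform", seed=3)


def circular_diff_deg(a, b):
    """Smallest absolute difference between undirected orientations (deg)."""
    d = (a - b) % 180.0
    return min(d, 180.0 - d)


@pytest.fixture
def gray_from_array():
    def _make(arr, source_id="test"):
        return GrayImage(pixels=np.asarray(arr, dtype=float),
                         source_id=source_id)
    return _make
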