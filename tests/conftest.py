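import numpy as np
import pytest

import liverlsm as L


@pytest.fixture(scope="session")
def liver_phantom_noiseless():
    return L.make_liver_phantom(L.PhantomSpec(noise_sigma=0.0))


@pytest.fixture(scope="session")
def small_disk_phantom():
    """A 128x128 bright disk on dark background; quick level-set fixture."""
    spec = L.PhantomSpec(
        shape=(128, 128),
        components=(L.Blob((64, 64), (44, 38), 0.8),),
        noise_sigma=0.0,
    )
    return L.make_liver_phantom(spec)


@pytest.fixture(scope="session")
def tumor_phantom_hard():
    """Low-contrast hypodense lesion under a 0.3 linear bias, noise 0.02."""
    return L.make_tumor_phantom(L.TumorPhantomSpec(seed=5))


@pytest.fixture(scope="session")
def tumor_phantom_clean():
    """High-contrast lesion, mild noise, no bias."""
    return L.make_tumor_phantom(
        L.TumorPhantomSpec(seed=7, contrast=0.25, bias_amplitude=0.0, noise_sigma=0.01)
    )


def random_mask(rng: np.random.Generator, shape, p=0.4) -> np.ndarray:
    """A random blobby binary mask (smoothed threshold of noise)."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), 2.0)
    mask = field > np.quantile(field, 1 - p)
    return mask.astype(np.uint8)
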