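import numpy as np
import pytest

from mseval import BinaryVolume


def vol_from_coords(coords, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), **meta):
    """BinaryVolume with foreground exactly at the given voxel coordinates."""
    occ = np.zeros(shape, dtype=bool)
    for c in coords:
        occ[tuple(c)] = True
    return BinaryVolume(occ, spacing=spacing, **meta)


def cube(corner, size, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    """Solid axis-aligned cube of `size` voxels per side at `corner`."""
    occ = np.zeros(shape, dtype=bool)
    sl = tuple(slice(c, c + size) for c in corner)
    occ[sl] = True
    return BinaryVolume(occ, spacing=spacing)


def random_blob_mask(rng, shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0),
                     density=0.5, sigma=1.5):
    """Random smooth binary mask: thresholded Gaussian-filtered noise.

    Produces a few irregular multi-voxel components plus scattered small
    ones — a harsher component-structure than sphere phantoms.
    """
    from scipy import ndimage as ndi

    noise = rng.standard_normal(shape)
    smooth = ndi.gaussian_filter(noise, sigma=sigma)
    thresh = np.quantile(smooth, 1.0 - 0.5 * density * rng.uniform(0.2, 1.0))
    return BinaryVolume(smooth > thresh, spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20160901)


@pytest.fixture(scope="session")
def small_phantom():
    """One fixed 48-cube phantom shared by the slower tests."""
    from mseval import PhantomConfig, generate_phantom

    cfg = PhantomConfig(grid_shape=(48, 48, 48), n_lesions=6, seed=11)
    return generate_phantom(cfg)
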