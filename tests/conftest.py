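import numpy as np
import pytest

from ftirfuse import phantom


@pytest.fixture(scope="session")
def fine_axis():
    """1 cm^-1 grid over the fingerprint region (both ratio bands on-grid)."""
    return np.arange(990.0, 1801.0, 1.0)


@pytest.fixture(scope="session")
def refs(fine_axis):
    return phantom.make_reference_spectra(fine_axis, seed=11)


@pytest.fixture(scope="session")
def refs_full():
    """References on the default acquisition grid (990-3798, 4 cm^-1)."""
    return phantom.make_reference_spectra(phantom.default_axis(), seed=11)


@pytest.fixture(scope="session")
def small_scene():
    """128x128 scene at 0.25 um; fast to render at a 4x grid ratio."""
    return phantom.make_scene((128, 128), seed=5)


@pytest.fixture(scope="session")
def small_cube_clean(small_scene, refs_full):
    """Distortion-free cube on a 32x32 grid (1.0 um pixels)."""
    return phantom.render_ftir(
        small_scene, refs_full, pixel_size_lr=1.0, psf_sigma=0.5,
        noise_sd=0.0, baseline_amp=0.0, scatter_amp=0.0, seed=6,
    )


@pytest.fixture(scope="session")
def small_cube_noisy(small_scene, refs_full):
    """Same scene with the default distortion levels."""
    return phantom.render_ftir(
        small_scene, refs_full, pixel_size_lr=1.0, psf_sigma=0.5,
        noise_sd=0.01, baseline_amp=0.1, scatter_amp=0.02, seed=6,
    )
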