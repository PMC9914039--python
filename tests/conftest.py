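import numpy as np
import pytest

from cbctiq import ImageStack, NoiseModel, PhantomConfig, default_inserts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def white_noise_stack(rng):
    """80 slices of pure white noise, sigma = 10 HU, 0.55 mm pixels."""
    vox = rng.normal(0.0, 10.0, size=(80, 160, 160))
    return ImageStack(vox, pixel_spacing_mm=(0.55, 0.55), slice_thickness_mm=1.991)


@pytest.fixture
def head_fbp_config():
    """Compact head-protocol-like uniform phantom with band-pass noise."""
    return PhantomConfig(
        matrix_size=320,
        pixel_spacing_mm=0.55,
        n_slices=40,
        noise_model=NoiseModel(target_sigma_hu=40.0, family="fbp", peak_frequency_mm=0.29),
        seed=7,
    )


@pytest.fixture
def insert_config():
    """Four-insert sensitometry phantom with mild blur and low noise."""
    return PhantomConfig(
        matrix_size=320,
        pixel_spacing_mm=0.55,
        n_slices=20,
        insert_specs=tuple(default_inserts()),
        psf_sigma_mm=0.5,
        noise_model=NoiseModel(target_sigma_hu=5.0, family="fbp", peak_frequency_mm=0.29),
        seed=21,
    )
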