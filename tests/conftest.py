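import numpy as np
import pytest

from follimetry import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A quick 512x512 phantom with 6 follicles, no noise, with truth labels."""
    spec = PhantomSpec(
        image_size=(512, 512),
        n_follicles=6,
        lumen_radius_range=(15.0, 30.0),
        epithelium_thickness_range=(12.0, 16.0),
        noise_sd=0.0,
        seed=3,
    )
    stack, truth, labels = generate_phantom(spec, return_labels=True)
    return spec, stack, truth, labels


@pytest.fixture(scope="session")
def mid_phantom():
    """A 1024x1024, 10-follicle phantom at default geometry, no noise."""
    spec = PhantomSpec(image_size=(1024, 1024), n_follicles=10, noise_sd=0.0, seed=42)
    stack, truth, labels = generate_phantom(spec, return_labels=True)
    return spec, stack, truth, labels


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 < radius**2
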