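import numpy as np
import pytest

from ihc_catscore import SyntheticImageSpec, generate_ihc_image
from ihc_catscore.stains import StainVectors, separate_stains


@pytest.fixture(scope="session")
def hdab():
    return StainVectors.hdab()


@pytest.fixture(scope="session")
def noiseless_field():
    """A small noiseless synthetic field shared across tests (seed-fixed)."""
    spec = SyntheticImageSpec(
        height=768, width=768, n_cells=200, noise_sd=0.0, seed=1, negative_fraction=0.65
    )
    rgb, truth = generate_ihc_image(spec)
    return spec, rgb, truth


@pytest.fixture(scope="session")
def noiseless_stains(noiseless_field):
    _, rgb, _ = noiseless_field
    return separate_stains(rgb)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
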