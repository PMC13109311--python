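import numpy as np
import pytest

from leafspec.synthdata import GeneratorConfig, simulate_leaf_spectra


@pytest.fixture(scope="session")
def linear_batch():
    """Noise-free linear benchmark: pigment -> spectrum map exactly affine."""
    return simulate_leaf_spectra(
        GeneratorConfig(n_samples=200, noise_sd=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def noisy_batch():
    """Default-noise linear benchmark (1 % of mean leaf reflectance)."""
    return simulate_leaf_spectra(GeneratorConfig(n_samples=200, seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
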