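import numpy as np
import pytest

from mavi.spectral_core import Spectrum, default_grid, preprocess
from mavi.synth_canopy import simulate_dataset
from mavi.vi_library import compute_index_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def smooth_random_spectrum(rng, low=0.05, high=0.6):
    """Random smooth positive spectrum on the working grid (random
    Fourier bumps, no sharp structure)."""
    grid = default_grid()
    x = (grid - grid[0]) / (grid[-1] - grid[0])
    y = np.zeros_like(x)
    for k in range(1, 6):
        y += rng.normal(0, 1.0 / k) * np.sin(2 * np.pi * k * x + rng.uniform(0, 2 * np.pi))
    y = (y - y.min()) / (y.max() - y.min())  # [0, 1]
    return Spectrum(grid, low + (high - low) * y)


@pytest.fixture(scope="session")
def sim90():
    """Default synthetic campaign: 90 samples x 9 VZAs, preprocessed."""
    return preprocess(simulate_dataset(reps=3, seed=7))


@pytest.fixture(scope="session")
def vitable90(sim90):
    return compute_index_table(sim90)
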