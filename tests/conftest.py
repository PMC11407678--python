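import numpy as np
import pytest

from orgscape import simgen
from orgscape.io_formats import SpectralWindow


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_windows():
    """A tiny 6-window, 2-spectrometer layout for fast spectral tests."""
    return [
        SpectralWindow(500 + 10 * i, 10.0, 1, 488.0) for i in range(3)
    ] + [SpectralWindow(600 + 10 * i, 10.0, 2, 561.0) for i in range(3)]


@pytest.fixture
def small_reference(small_windows):
    """Three overlapping Gaussian fluorophores on the tiny layout."""
    return simgen.gaussian_emission_reference(
        ["F1", "F2", "F3"], [505.0, 525.0, 612.0], sd_nm=12.0,
        windows=small_windows,
    )


@pytest.fixture
def organelle_table():
    """Small noiseless 7-class feature table with known class labels."""
    cfg = simgen.seven_organelle_config(n_particles=700, seed=11)
    gt = simgen.sample_particles(cfg)
    return simgen.make_feature_matrix(gt, noise_sd=0.1, n_batches=3, seed=11)
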