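import numpy as np
import pytest

from astroseg.hierarchy import BranchType
from astroseg.synthgen import ArborSpec, generate_arbor, place_mitochondria, render_image

MITO_COUNTS = {
    BranchType.SOMA_PRIMARY: 3,
    BranchType.SECONDARY: 5,
    BranchType.FINE: 8,
    BranchType.TERMINAL: 3,
}


def make_benchmark(seed: int, noise_sd: float = 0.0):
    """One synthetic two-channel benchmark with ground truth."""
    gt = generate_arbor(ArborSpec(seed=seed))
    gt = place_mitochondria(gt, MITO_COUNTS, seed=seed + 100)
    cell, mito, labels = render_image(gt, noise_sd=noise_sd, seed=seed + 200)
    return gt, cell, mito, labels


@pytest.fixture(scope="session")
def benchmark17():
    """Default zero-noise benchmark (seed 17) shared across tests."""
    return make_benchmark(17)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
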