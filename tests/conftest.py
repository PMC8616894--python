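import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    from mrcontrast.phantom import generate_tissue_map

    return generate_tissue_map(seed=7, height=64, width=64, n_structures=6)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Fully paired 32x32 dataset shared by training-level tests."""
    from mrcontrast.phantom import make_synthetic_dataset

    return make_synthetic_dataset(seed=3, n_subjects=24, slices_per_subject=2,
                                  pair_fraction=1.0, height=32, width=32)
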