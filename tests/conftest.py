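import numpy as np
import pytest

from spectra_emu import (
    BandGrid,
    EmulatorConfig,
    LabeledSpectralDataset,
    SplitSpec,
    generate_dataset,
    split_dataset,
    train_emulator,
)


@pytest.fixture
def small_grid():
    return BandGrid(np.array([450.0, 550.0, 670.0, 850.0]), "toy4", 1.0)


@pytest.fixture
def tiny_dataset(small_grid):
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 5, (8, 2))
    Y = rng.uniform(0.05, 0.6, (8, 4))
    return LabeledSpectralDataset(
        variable_names=["LAI", "LCC"], X=X, Y=Y, band_grid=small_grid
    )


@pytest.fixture(scope="session")
def chris_dataset():
    """Noisy synthetic dataset on the 62-band VNIR grid."""
    return generate_dataset(80, "chris62", seed=11)


@pytest.fixture(scope="session")
def chris_split(chris_dataset):
    return split_dataset(chris_dataset, SplitSpec(0.8, seed=4))


@pytest.fixture(scope="session")
def krr_emulator(chris_split):
    train, _ = chris_split
    return train_emulator(train, EmulatorConfig(method="KRR", seed=3))
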