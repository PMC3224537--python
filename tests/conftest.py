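import numpy as np
import pytest

from mammocad.datatypes import ROIDataset
from mammocad.synthetic import SynthParams, generate_dataset


@pytest.fixture(scope="session")
def small_dataset() -> ROIDataset:
    """60-sample synthetic mass/non-mass dataset at moderate contrast."""
    return generate_dataset(
        {"mass": 30, "non-mass": 30}, SynthParams(blob_contrast=0.8, seed=11)
    )


@pytest.fixture(scope="session")
def separable_dataset() -> ROIDataset:
    """High-contrast 200-sample dataset for end-to-end sanity checks."""
    return generate_dataset(
        {"mass": 100, "non-mass": 100}, SynthParams(blob_contrast=1.5, seed=7)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
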