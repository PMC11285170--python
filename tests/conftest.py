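import numpy as np
import pytest
from hypothesis import settings

from cellgate.preprocess import RawDataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from cellgate.synthdata import SynthConfig, generate_atac


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_pair():
    """Small, quickly generated source/target pair: 3 known + 1 novel type."""
    return generate_atac(SynthConfig(n_source=90, n_target=90, n_peaks=240,
                                     known_types=3, n_unknown_types=1,
                                     marker_peaks_per_type=40, seed=7))


@pytest.fixture
def atac_raw(rng):
    matrix = rng.integers(0, 4, size=(30, 12)).astype(float)
    return RawDataset(
        matrix=matrix,
        feature_ids=[f"chr1:{100 * i}-{100 * i + 80}" for i in range(12)],
        cell_ids=[f"c{i}" for i in range(30)],
        labels=[f"t{i % 3}" for i in range(30)],
        modality="atac",
    )
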